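# End-to-end synthetic study: rheology fits, array segmentation, assay stats.
# Run with:  orgaprint run --config configs/demo.yaml --out scratch/demo
seed: 42
stages:
  - name: flow
    kind: simulate_flow
    params:
      hb: [10.0, 2.0, 0.5]     # sigma_y Pa, K Pa*s^n, n
      noise_frac: 0.01
      n_points: 30
  - name: hb
    kind: fit_hb
    inputs: {flow: flow.flow}
  - name: relax
    kind: simulate_relaxation
    params:
      kww: [300.0, 0.6, 0.05]  # tau s, beta, residual fraction
      sigma0_Pa: 4.0
      duration_s: 3600.0
      noise_frac: 0.005
  - name: kww
    kind: fit_kww
    inputs: {relaxation: relax.relaxation}
  - name: sweep
    kind: simulate_sweep
    params:
      yield_strain: 0.4
      G0_store_Pa: 200.0
      G0_loss_Pa: 40.0
  - name: yield
    kind: crossover
    inputs: {sweep: sweep.sweep}
  - name: array
    kind: simulate_image
    params:
      mode: printed
      n_organoids: 9
      shape_px: [900, 900]
      um_per_px: 2.0
      radius_mean_um: 100.0
      radius_cv: 0.05
      pitch_um: 750.0
      noise_sd: 0.02
  - name: morpho
    kind: segment_measure
    inputs: {image: array.image}
    params:
      min_area_um2: 5000.0
      exclude_border: false
  - name: tube
    kind: simulate_tube
    params:
      baseline_diam_um: 100.0
      peak_strain: 0.3
  - name: tubemetrics
    kind: tube_metrics
    inputs: {masks: tube.masks}
  - name: assay
    kind: simulate_assay
    params:
      n_per_condition: 200
  - name: power
    kind: power_stats
    inputs: {readouts: assay.readouts}
    params:
      n_grid: [2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25, 30, 40, 50]
      iterations: 512
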