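# orgaprint

Quantitative analysis for granular-gel organoid bioprinting: rheology of
yield-stress support matrices, organoid morphometrics from microscopy masks,
and the assay-sensitivity statistics that compare bioprinted organoid arrays
with manually seeded cultures.

Embedded bioprinting deposits cells into a jammed microgel slurry that
behaves as a solid at rest and flows above a yield stress. Whether such a
matrix supports organoid morphogenesis depends on quantities that must be
measured, not assumed: the yield stress and flow index of the support bath,
how fast it relaxes imposed stress over the hours on which tissues grow, and
how much more reproducible the resulting arrays make a downstream phenotypic
assay. This package implements that entire measurement chain, together with a
synthetic-data module that generates every input with known ground truth, so
the whole pipeline is testable end to end without any raw instrument data.

## Models

* **Herschel–Bulkley flow curves.** Unidirectional shear data (γ̇, σ) are fit
  to σ = σ_y + K·γ̇ⁿ by bounded nonlinear least squares with multi-start over
  the flow index. The yield stress σ_y is the model's zero-shear-rate
  intercept.
* **Amplitude-sweep yielding.** The strain at which G′ (storage) crosses
  below G″ (loss) marks yielding; the crossover is interpolated in log–log
  space between bracketing samples.
* **Stress relaxation (KWW).** Normalized traces are fit to the stretched
  exponential N(t) = r + (1−r)·exp(−(t/τ)^β) with a free residual plateau r;
  the average relaxation time is ⟨τ⟩ = (τ/β)·Γ(1/β). Fraction relaxed and
  residual stress are read off the normalized and raw tails.
* **Morphometrics.** Gaussian blur → adaptive threshold → per-object half-max
  refinement → size (5,000 µm² default) and border filters; area, perimeter
  (smoothed boundary-polygon length), circularity 4πA/P², radial-profile
  crypt counting, perimeter strain over time windows, tube diameter =
  thresholded area / tube length, and lineage boundary occupancy against a
  composition baseline.
* **Assay sensitivity.** Coefficient of variation, two-sided Mann–Whitney U
  (exact permutation distribution for small tie-free comparisons), the
  D'Agostino–Pearson normality test, bootstrap p-vs-n curves (mean ± s.e.m.
  of p over 512 resampled size-n comparisons per arm), the smallest n whose
  mean p clears α, and post-hoc Welch two-sample sizes by noncentral-t
  iteration.

## Worked example

```python
import numpy as np
from orgaprint import synthetic, rheology, assay_stats

# a noisy flow curve of a sigma_y = 10 Pa gel, and its fit
spec = synthetic.RheologySimSpec(hb=(10.0, 2.0, 0.5), noise_frac=0.01,
                                 grid=np.logspace(-2, 2, 30), seed=7)
curve, truth = synthetic.gen_flow_curve(spec)
fit = rheology.fit_herschel_bulkley(curve)
print(f"yield stress: {fit.sigma_y:.2f} Pa (true {truth.sigma_y:.1f}), "
      f"K={fit.K:.2f}, n={fit.n_exp:.3f}")

# printed vs manual assay sensitivity on calibrated synthetic readouts
samples = synthetic.gen_assay_readouts(
    synthetic.default_assay_spec(n_per_condition=200, seed=7))
for mod in ("printed", "manual"):
    curve = assay_stats.bootstrap_power_curve(
        samples[(mod, "treated")].values, samples[(mod, "untreated")].values,
        n_grid=np.arange(2, 61), iterations=512, seed=7)
    n_star = assay_stats.min_n_below_alpha(curve, 0.05)
    print(f"{mod}: mean p < 0.05 from n = {n_star} organoid comparisons per arm")
```

prints

```
yield stress: 10.03 Pa (true 10.0), K=1.90, n=0.511
printed: mean p < 0.05 from n = 4 organoid comparisons per arm
manual: mean p < 0.05 from n = 23 organoid comparisons per arm
```

The fitted parameters recover the generating gel within the 1% instrument
noise. The two sensitivity curves show the point of the bioprinted arrays:
with low-dispersion printed readouts (CVs of 48%/58%) a treatment effect is
resolvable from a handful of organoid comparisons, while the high-dispersion
manual condition (CVs of 127%/174%, same relative effect scaled 3.7× smaller)
needs an order of magnitude more.

The same operations are available from the shell, e.g.:

```sh
orgaprint simulate --kind flow --seed 3 --out out/
orgaprint rheology fit --model hb --in out/flow_flow.csv --out out/hb.json
orgaprint run --config configs/demo.yaml --out out/demo
```

The demo config runs the full synthetic study (rheology fits, array
segmentation, tube metrics, power statistics) and writes a machine-readable
manifest; reruns with the same seed are byte-identical.

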