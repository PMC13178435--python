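"""Config-driven orchestration: simulate -> segment/fit -> statistics.

A run is described by a YAML config with a global seed and an ordered list of
stages.  Each stage has a ``name``, a ``kind`` from the registry below, a
``params`` mapping, and optionally ``inputs`` referring to outputs of earlier
stages (``"<stage>.<output-key>"``) or to existing files.  The whole config is
validated before any stage runs; execution writes every output under the run
directory and a ``manifest.json`` linking outputs to inputs, parameters and
the per-stage seed (derived deterministically from the global seed and the
stage index, so one integer reproduces the entire run).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional

import numpy as np
import yaml

from . import assay_stats, io, morphometrics, rheology, synthetic
from .datatypes import PowerSpec

__all__ = ["RunConfig", "StageSpec", "run", "load_config", "STAGE_KINDS"]


@dataclass(frozen=True)
class StageSpec:
    name: str
    kind: str
    params: dict = field(default_factory=dict)
    inputs: Dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class RunConfig:
    seed: int
    stages: List[StageSpec]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "params": dict(s.params),
                    "inputs": dict(s.inputs),
                }
                for s in self.stages
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        stages = [
            StageSpec(
                name=s["name"],
                kind=s["kind"],
                params=dict(s.get("params", {})),
                inputs=dict(s.get("inputs", {})),
            )
            for s in d.get("stages", [])
        ]
        return cls(seed=int(d.get("seed", 0)), stages=stages)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _stage_seed(global_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([global_seed, index]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# Stage handlers.  Each returns {output-key: written Path}.


def _simulate_flow(stage, seed, out_dir, resolve):
    p = stage.params
    grid = np.logspace(
        p.get("rate_log10_min", -2), p.get("rate_log10_max", 2), p.get("n_points", 30)
    )
    spec = synthetic.RheologySimSpec(
        hb=tuple(p.get("hb", (10.0, 2.0, 0.5))),
        noise_frac=p.get("noise_frac", 0.01),
        grid=grid,
        seed=seed,
    )
    curve, truth = synthetic.gen_flow_curve(spec)
    out = out_dir / f"{stage.name}_flow.csv"
    io.write_flow_csv(curve, out)
    truth_path = out_dir / f"{stage.name}_truth.json"
    truth_path.write_text(
        json.dumps(
            {"sigma_y_Pa": truth.sigma_y, "K": truth.K, "n_exp": truth.n_exp}, indent=2
        )
        + "\n"
    )
    return {"flow": out, "truth": truth_path}


def _simulate_relaxation(stage, seed, out_dir, resolve):
    p = stage.params
    spec = synthetic.RheologySimSpec(
        kww=tuple(p.get("kww", (300.0, 0.6, 0.05))),
        noise_frac=p.get("noise_frac", 0.01),
        seed=seed,
    )
    trace = synthetic.gen_relaxation_trace(
        spec,
        sigma0=p.get("sigma0_Pa", 4.0),
        duration=p.get("duration_s", 3600.0),
        applied_strain=p.get("applied_strain", 0.1),
    )
    out = out_dir / f"{stage.name}_relaxation.csv"
    io.write_relaxation_csv(trace, out)
    truth_path = out_dir / f"{stage.name}_truth.json"
    tau, beta, resid = spec.kww
    truth_path.write_text(
        json.dumps({"tau_s": tau, "beta": beta, "residual_frac": resid}, indent=2) + "\n"
    )
    return {"relaxation": out, "truth": truth_path}


def _simulate_sweep(stage, seed, out_dir, resolve):
    p = stage.params
    grid = np.logspace(
        p.get("strain_log10_min", -3), p.get("strain_log10_max", 1), p.get("n_points", 40)
    )
    sweep = synthetic.gen_amplitude_sweep(
        yield_strain=p.get("yield_strain", 0.4),
        G0_store=p.get("G0_store_Pa", 200.0),
        G0_loss=p.get("G0_loss_Pa", 40.0),
        grid=grid,
        noise_frac=p.get("noise_frac", 0.0),
        seed=seed,
    )
    out = out_dir / f"{stage.name}_sweep.csv"
    io.write_sweep_csv(sweep, out)
    return {"sweep": out}


def _simulate_image(stage, seed, out_dir, resolve):
    p = dict(stage.params)
    p.setdefault("shape_px", (1024, 1024))
    spec = synthetic.ImageSimSpec(
        shape_px=tuple(p["shape_px"]),
        um_per_px=p.get("um_per_px", 2.0),
        mode=p.get("mode", "printed"),
        n_organoids=p.get("n_organoids", 9),
        radius_mean_um=p.get("radius_mean_um", 100.0),
        radius_cv=p.get("radius_cv", 0.05),
        lobes=p.get("lobes", 0),
        lobe_amp=p.get("lobe_amp", 0.0),
        pitch_um=p.get("pitch_um", 750.0),
        noise_sd=p.get("noise_sd", 0.02),
        blur_sigma_um=p.get("blur_sigma_um", 4.0),
        seed=seed,
    )
    img, truth = synthetic.gen_organoid_image(spec)
    out = out_dir / f"{stage.name}_image.tif"
    io.write_image(img, out)
    truth_path = out_dir / f"{stage.name}_truth.csv"
    truth.to_csv(truth_path, index=False, float_format="%.10g")
    return {"image": out, "truth": truth_path}


def _simulate_assay(stage, seed, out_dir, resolve):
    p = stage.params
    if "conditions" in p:
        conditions = {
            (c["modality"], c["treatment"]): synthetic.ConditionSpec(
                mean=c["mean"], cv=c["cv"], n=c.get("n", 200)
            )
            for c in p["conditions"]
        }
        spec = synthetic.AssaySimSpec(
            conditions=conditions, family=p.get("family", "lognormal"), seed=seed
        )
    else:
        spec = synthetic.default_assay_spec(
            n_per_condition=p.get("n_per_condition", 200),
            seed=seed,
            family=p.get("family", "lognormal"),
        )
    samples = synthetic.gen_assay_readouts(spec)
    out = out_dir / f"{stage.name}_readouts.csv"
    io.write_readouts_csv(samples, out)
    return {"readouts": out}


def _simulate_tube(stage, seed, out_dir, resolve):
    p = stage.params
    spec = synthetic.TubeSimSpec(
        baseline_diam_um=p.get("baseline_diam_um", 100.0),
        peak_strain=p.get("peak_strain", 0.3),
        period_s=p.get("period_s", 20.0),
        n_frames=p.get("n_frames", 80),
        duty=p.get("duty", 0.5),
        um_per_px=p.get("um_per_px", 1.0),
        seed=seed,
    )
    stack, truth = synthetic.gen_tube_series(spec)
    out = out_dir / f"{stage.name}_masks.tif"
    import tifffile

    tifffile.imwrite(out, stack.astype(np.uint8))
    truth_path = out_dir / f"{stage.name}_truth.csv"
    truth.to_csv(truth_path, index=False, float_format="%.10g")
    meta = out_dir / f"{stage.name}_masks.tif.yaml"
    meta.write_text(yaml.safe_dump({"um_per_px": float(spec.um_per_px)}))
    return {"masks": out, "truth": truth_path}


def _fit_hb(stage, seed, out_dir, resolve):
    curve = io.read_flow_csv(resolve(stage.inputs["flow"]))
    fit = rheology.fit_herschel_bulkley(curve)
    out = out_dir / f"{stage.name}_hb.json"
    out.write_text(
        json.dumps(
            {
                "sigma_y_Pa": fit.sigma_y,
                "K": fit.K,
                "n_exp": fit.n_exp,
                "rss_Pa2": fit.rss,
            },
            indent=2,
        )
        + "\n"
    )
    return {"fit": out}


def _fit_kww(stage, seed, out_dir, resolve):
    trace = io.read_relaxation_csv(resolve(stage.inputs["relaxation"]))
    fit = rheology.fit_stretched_exponential(trace)
    frac = rheology.fraction_relaxed(trace, trace.time[-1])
    resid = rheology.residual_stress(trace)
    out = out_dir / f"{stage.name}_kww.json"
    out.write_text(
        json.dumps(
            {
                "tau_s": fit.tau,
                "beta": fit.beta,
                "residual_frac": fit.residual_frac,
                "mean_tau_s": fit.mean_tau,
                "r2": fit.r2,
                "beta_at_bound": fit.beta_at_bound,
                "fraction_relaxed_at_end": frac,
                "residual_stress_Pa": resid,
            },
            indent=2,
        )
        + "\n"
    )
    return {"fit": out}


def _crossover(stage, seed, out_dir, resolve):
    sweep = io.read_sweep_csv(resolve(stage.inputs["sweep"]))
    strain, stress = rheology.crossover_strain(sweep)
    out = out_dir / f"{stage.name}_crossover.json"
    out.write_text(
        json.dumps({"strain": strain, "stress_Pa": stress}, indent=2) + "\n"
    )
    return {"crossover": out}


def _segment_measure(stage, seed, out_dir, resolve):
    p = stage.params
    img = io.read_image(resolve(stage.inputs["image"]))
    mask = morphometrics.segment_organoids(
        img,
        blur_sigma_um=p.get("blur_sigma_um", 10.0),
        min_area_um2=p.get("min_area_um2", 5000.0),
        exclude_border=p.get("exclude_border", True),
        window_um=p.get("window_um", 400.0),
    )
    records = morphometrics.measure_organoids(
        mask, with_crypts=p.get("with_crypts", False)
    )
    mask_path = out_dir / f"{stage.name}_mask.tif"
    io.write_label_mask(mask, mask_path)
    csv_path = out_dir / f"{stage.name}_organoids.csv"
    io.write_records_csv(records, csv_path)
    return {"mask": mask_path, "organoids": csv_path}


def _tube_metrics(stage, seed, out_dir, resolve):
    import tifffile

    mask_path = resolve(stage.inputs["masks"])
    stack = tifffile.imread(mask_path)
    meta = Path(str(mask_path) + ".yaml")
    um_per_px = (
        float(yaml.safe_load(meta.read_text())["um_per_px"]) if meta.exists() else 1.0
    )
    df = morphometrics.tube_metrics(stack, um_per_px=um_per_px)
    out = out_dir / f"{stage.name}_tube.csv"
    df.to_csv(out, index=False, float_format="%.10g")
    return {"tube": out}


def _power_stats(stage, seed, out_dir, resolve):
    p = stage.params
    samples = io.read_readouts_csv(resolve(stage.inputs["readouts"]))
    summary = assay_stats.effect_summary(samples)
    n_grid = np.asarray(p.get("n_grid", list(range(2, 31))), dtype=int)
    iterations = p.get("iterations", 512)
    alpha = p.get("alpha", 0.05)
    outputs = {}
    min_n = {}
    for modality in ("printed", "manual"):
        curve = assay_stats.bootstrap_power_curve(
            samples[(modality, "treated")].values,
            samples[(modality, "untreated")].values,
            n_grid=n_grid,
            iterations=iterations,
            seed=seed,
        )
        path = out_dir / f"{stage.name}_{modality}_curve.csv"
        io.write_power_curve(curve, path)
        outputs[f"curve_{modality}"] = path
        n_star = assay_stats.min_n_below_alpha(curve, alpha)
        min_n[modality] = n_star if n_star is not None else "not reached"
    # post-hoc Welch sample size from the observed printed/manual moments
    sizes = {}
    for modality in ("printed", "manual"):
        t = samples[(modality, "treated")].values
        u = samples[(modality, "untreated")].values
        sizes[modality] = assay_stats.required_sample_size(
            PowerSpec(
                mean_a=float(t.mean()),
                mean_b=float(u.mean()),
                sd_a=float(t.std(ddof=1)),
                sd_b=float(u.std(ddof=1)),
                alpha=alpha,
                power=p.get("power", 0.8),
            )
        )
    report = {
        "per_condition": summary["table"].to_dict(orient="records"),
        "delta_printed": summary["delta_printed"],
        "delta_manual": summary["delta_manual"],
        "delta_ratio": summary["delta_ratio"],
        "min_n_below_alpha": min_n,
        "required_sample_size": sizes,
        "alpha": alpha,
        "iterations": iterations,
    }
    out = out_dir / f"{stage.name}_stats.json"
    out.write_text(json.dumps(report, indent=2) + "\n")
    outputs["stats"] = out
    return outputs


STAGE_KINDS: Dict[str, Callable] = {
    "simulate_flow": _simulate_flow,
    "simulate_relaxation": _simulate_relaxation,
    "simulate_sweep": _simulate_sweep,
    "simulate_image": _simulate_image,
    "simulate_assay": _simulate_assay,
    "simulate_tube": _simulate_tube,
    "fit_hb": _fit_hb,
    "fit_kww": _fit_kww,
    "crossover": _crossover,
    "segment_measure": _segment_measure,
    "tube_metrics": _tube_metrics,
    "power_stats": _power_stats,
}

_REQUIRED_INPUTS = {
    "fit_hb": ["flow"],
    "fit_kww": ["relaxation"],
    "crossover": ["sweep"],
    "segment_measure": ["image"],
    "tube_metrics": ["masks"],
    "power_stats": ["readouts"],
}


def _validate(config: RunConfig) -> None:
    """Pre-flight schema check; raises before any stage runs."""
    seen: Dict[str, set] = {}
    names = set()
    for stage in config.stages:
        if stage.kind not in STAGE_KINDS:
            raise ValueError(f"stage {stage.name!r}: unknown kind {stage.kind!r}")
        if stage.name in names:
            raise ValueError(f"duplicate stage name {stage.name!r}")
        names.add(stage.name)
        for key in _REQUIRED_INPUTS.get(stage.kind, []):
            if key not in stage.inputs:
                raise ValueError(f"stage {stage.name!r}: missing input {key!r}")
        for key, ref in stage.inputs.items():
            if "." in ref:
                src, out_key = ref.split(".", 1)
                if src not in seen or out_key not in seen[src]:
                    raise ValueError(
                        f"stage {stage.name!r}: input {key!r} refers to "
                        f"{ref!r} which no earlier stage produces"
                    )
            elif not Path(ref).exists():
                raise ValueError(
                    f"stage {stage.name!r}: input file {ref!r} does not exist"
                )
        # declared output keys per kind (known statically for reference checks)
        seen[stage.name] = _OUTPUT_KEYS[stage.kind]


_OUTPUT_KEYS = {
    "simulate_flow": {"flow", "truth"},
    "simulate_relaxation": {"relaxation", "truth"},
    "simulate_sweep": {"sweep"},
    "simulate_image": {"image", "truth"},
    "simulate_assay": {"readouts"},
    "simulate_tube": {"masks", "truth"},
    "fit_hb": {"fit"},
    "fit_kww": {"fit"},
    "crossover": {"crossover"},
    "segment_measure": {"mask", "organoids"},
    "tube_metrics": {"tube"},
    "power_stats": {"curve_printed", "curve_manual", "stats"},
}


def run(config: RunConfig, out_dir, seed: Optional[int] = None) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest.

    ``seed`` overrides the config's global seed.  A stage failure stops the
    run and leaves a partial manifest with the failure recorded.
    """
    _validate(config)
    global_seed = config.seed if seed is None else int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    produced: Dict[str, Dict[str, Path]] = {}

    def resolve(ref: str) -> Path:
        if "." in ref:
            src, key = ref.split(".", 1)
            if src in produced and key in produced[src]:
                return produced[src][key]
        return Path(ref)

    manifest = {"seed": global_seed, "stages": []}
    for index, stage in enumerate(config.stages):
        stage_seed = _stage_seed(global_seed, index)
        entry = {
            "name": stage.name,
            "kind": stage.kind,
            "seed": stage_seed,
            "params": dict(stage.params),
            "inputs": {k: str(resolve(v)) for k, v in stage.inputs.items()},
        }
        t0 = time.monotonic()
        try:
            outputs = STAGE_KINDS[stage.kind](stage, stage_seed, out_dir, resolve)
        except Exception as exc:
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            entry["wall_clock_s"] = time.monotonic() - t0
            manifest["stages"].append(entry)
            (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
            raise
        entry["status"] = "ok"
        entry["wall_clock_s"] = time.monotonic() - t0
        entry["outputs"] = {k: str(v) for k, v in outputs.items()}
        manifest["stages"].append(entry)
        produced[stage.name] = outputs
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
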