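"""File formats: plain-CSV trace dialects, TIFF images with YAML scale sidecars.

CSV dialects (one header line, stable column names):

* flow curve:        ``shear_rate_1_per_s,stress_Pa``
* amplitude sweep:   ``strain,g_store_Pa,g_loss_Pa``
* relaxation trace:  ``time_s,stress_Pa``
* assay readouts:    ``modality,treatment,value``
* power curve:       ``n,mean_p,sem_p`` (+ JSON metadata next to it)
* organoid records:  ``label,area_um2,perimeter_um,circularity,crypt_count,
                       centroid_row,centroid_col``

Images are written as 16-bit TIFF (grey levels clipped to [0, 1] and scaled to
the full range) and label masks as integer TIFF; the physical pixel scale is
recorded in a ``<name>.yaml`` sidecar because TIFF resolution tags round-trip
poorly across tools.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import (
    AmplitudeSweep,
    ConditionSample,
    FlowCurve,
    LabelMask,
    MicroscopyImage,
    OrganoidRecord,
    PowerCurve,
    RelaxationTrace,
)

__all__ = [
    "read_flow_csv",
    "write_flow_csv",
    "read_sweep_csv",
    "write_sweep_csv",
    "read_relaxation_csv",
    "write_relaxation_csv",
    "read_readouts_csv",
    "write_readouts_csv",
    "write_power_curve",
    "read_power_curve",
    "write_records_csv",
    "write_image",
    "read_image",
    "write_label_mask",
    "read_label_mask",
]

_FLOAT_FMT = "%.10g"  # fixed format so reruns are byte-identical


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# --- rheometry traces ------------------------------------------------------


def write_flow_csv(curve: FlowCurve, path) -> None:
    _write_table(
        pd.DataFrame(
            {"shear_rate_1_per_s": curve.shear_rate, "stress_Pa": curve.stress}
        ),
        Path(path),
    )


def read_flow_csv(path, temperature: float = 4.0) -> FlowCurve:
    df = pd.read_csv(path)
    return FlowCurve(
        shear_rate=df["shear_rate_1_per_s"].to_numpy(),
        stress=df["stress_Pa"].to_numpy(),
        temperature=temperature,
    )


def write_sweep_csv(sweep: AmplitudeSweep, path) -> None:
    _write_table(
        pd.DataFrame(
            {
                "strain": sweep.strain,
                "g_store_Pa": sweep.g_store,
                "g_loss_Pa": sweep.g_loss,
            }
        ),
        Path(path),
    )


def read_sweep_csv(path, frequency: float = 1.0) -> AmplitudeSweep:
    df = pd.read_csv(path)
    return AmplitudeSweep(
        strain=df["strain"].to_numpy(),
        g_store=df["g_store_Pa"].to_numpy(),
        g_loss=df["g_loss_Pa"].to_numpy(),
        frequency=frequency,
    )


def write_relaxation_csv(trace: RelaxationTrace, path) -> None:
    _write_table(
        pd.DataFrame({"time_s": trace.time, "stress_Pa": trace.stress}), Path(path)
    )


def read_relaxation_csv(
    path, applied_strain: float = 0.1, temperature: float = 4.0
) -> RelaxationTrace:
    df = pd.read_csv(path)
    return RelaxationTrace(
        time=df["time_s"].to_numpy(),
        stress=df["stress_Pa"].to_numpy(),
        applied_strain=applied_strain,
        temperature=temperature,
    )


# --- assay readouts --------------------------------------------------------


def write_readouts_csv(
    samples: Dict[Tuple[str, str], ConditionSample], path
) -> None:
    frames = []
    for key in sorted(samples):
        s = samples[key]
        frames.append(
            pd.DataFrame(
                {
                    "modality": s.modality,
                    "treatment": s.treatment,
                    "value": s.values,
                }
            )
        )
    _write_table(pd.concat(frames, ignore_index=True), Path(path))


def read_readouts_csv(path) -> Dict[Tuple[str, str], ConditionSample]:
    df = pd.read_csv(path)
    out: Dict[Tuple[str, str], ConditionSample] = {}
    for (modality, treatment), sub in df.groupby(["modality", "treatment"]):
        out[(modality, treatment)] = ConditionSample(
            modality=modality, treatment=treatment, values=sub["value"].to_numpy()
        )
    return out


# --- power curves ----------------------------------------------------------


def write_power_curve(curve: PowerCurve, csv_path, test_name: str = "mann-whitney") -> None:
    csv_path = Path(csv_path)
    _write_table(
        pd.DataFrame(
            {"n": curve.n_grid, "mean_p": curve.mean_p, "sem_p": curve.sem_p}
        ),
        csv_path,
    )
    meta = {
        "iterations": int(curve.iterations),
        "seed": int(curve.seed),
        "test": test_name,
        "saturated_n": [int(n) for n in curve.n_grid[curve.saturated]],
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_power_curve(csv_path) -> PowerCurve:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta_path = csv_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    n_grid = df["n"].to_numpy(dtype=int)
    saturated = np.isin(n_grid, np.asarray(meta.get("saturated_n", []), dtype=int))
    return PowerCurve(
        n_grid=n_grid,
        mean_p=df["mean_p"].to_numpy(),
        sem_p=df["sem_p"].to_numpy(),
        iterations=int(meta.get("iterations", 0) or 1),
        seed=int(meta.get("seed", 0)),
        saturated=saturated,
    )


# --- morphometrics tables --------------------------------------------------


def write_records_csv(records: List[OrganoidRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "label": r.label,
                "area_um2": r.area,
                "perimeter_um": r.perimeter,
                "circularity": r.circularity,
                "crypt_count": r.crypt_count,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
            }
            for r in records
        ],
        columns=[
            "label",
            "area_um2",
            "perimeter_um",
            "circularity",
            "crypt_count",
            "centroid_row",
            "centroid_col",
        ],
    )
    _write_table(df, Path(path))


# --- images ----------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_image(img: MicroscopyImage, path) -> None:
    """Write grey levels as 16-bit TIFF plus a YAML sidecar with the scale."""
    path = Path(path)
    levels = np.clip(img.pixels, 0.0, 1.0)
    tifffile.imwrite(path, (levels * 65535).round().astype(np.uint16))
    _sidecar(path).write_text(yaml.safe_dump({"um_per_px": float(img.um_per_px)}))


def read_image(path, um_per_px: float = None) -> MicroscopyImage:
    path = Path(path)
    raw = tifffile.imread(path)
    data = raw.astype(float)
    if np.issubdtype(raw.dtype, np.integer):
        data = data / 65535.0
    if um_per_px is None:
        side = _sidecar(path)
        if not side.exists():
            raise ValueError(
                f"no pixel scale: pass um_per_px or provide sidecar {side.name}"
            )
        um_per_px = float(yaml.safe_load(side.read_text())["um_per_px"])
    return MicroscopyImage(pixels=data, um_per_px=um_per_px)


def write_label_mask(mask: LabelMask, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.labels.astype(np.int32))
    _sidecar(path).write_text(yaml.safe_dump({"um_per_px": float(mask.um_per_px)}))


def read_label_mask(path, um_per_px: float = None) -> LabelMask:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    if um_per_px is None:
        side = _sidecar(path)
        if not side.exists():
            raise ValueError(
                f"no pixel scale: pass um_per_px or provide sidecar {side.name}"
            )
        um_per_px = float(yaml.safe_load(side.read_text())["um_per_px"])
    return LabelMask(labels=labels, um_per_px=um_per_px)
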