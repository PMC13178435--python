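"""Core measurement containers shared across the rheology, imaging and assay modules.

All containers are thin dataclasses around NumPy arrays.  They validate their
own physical invariants (monotone grids, positive moduli, matching lengths) at
construction so that every downstream fit can assume well-formed input.
Physical units are fixed by convention and written into field names or
docstrings: stresses in Pa, times in s, shear rates in 1/s, lengths in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FlowCurve",
    "AmplitudeSweep",
    "RelaxationTrace",
    "HBParams",
    "StretchedExpFit",
    "MicroscopyImage",
    "LabelMask",
    "OrganoidRecord",
    "TrackedSeries",
    "ConditionSample",
    "PowerCurve",
    "PowerSpec",
]


def _as_1d(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class FlowCurve:
    """Unidirectional shear measurement: stress (Pa) vs shear rate (1/s).

    Shear rates must be strictly positive and increasing; at least four points
    are required so a three-parameter yield-stress model remains identifiable.
    """

    shear_rate: np.ndarray
    stress: np.ndarray
    temperature: float = 4.0  # deg C, metadata only

    def __post_init__(self) -> None:
        gd = _as_1d(self.shear_rate, "shear_rate")
        st = _as_1d(self.stress, "stress")
        if len(gd) != len(st):
            raise ValueError("shear_rate and stress must have equal length")
        if len(gd) < 4:
            raise ValueError("flow curve needs at least 4 points")
        if np.any(gd <= 0):
            raise ValueError("shear rates must be strictly positive")
        if np.any(np.diff(gd) <= 0):
            raise ValueError("shear rates must be strictly increasing")
        object.__setattr__(self, "shear_rate", gd)
        object.__setattr__(self, "stress", st)


@dataclass(frozen=True)
class AmplitudeSweep:
    """Oscillatory amplitude sweep: storage/loss moduli (Pa) vs strain amplitude."""

    strain: np.ndarray
    g_store: np.ndarray
    g_loss: np.ndarray
    frequency: float = 1.0  # Hz, metadata

    def __post_init__(self) -> None:
        s = _as_1d(self.strain, "strain")
        gp = _as_1d(self.g_store, "g_store")
        gl = _as_1d(self.g_loss, "g_loss")
        if not (len(s) == len(gp) == len(gl)):
            raise ValueError("strain, g_store and g_loss must have equal length")
        if len(s) < 4:
            raise ValueError("amplitude sweep needs at least 4 points")
        if np.any(np.diff(s) <= 0):
            raise ValueError("strains must be strictly increasing")
        if np.any(gp <= 0) or np.any(gl <= 0):
            raise ValueError("moduli must be positive")
        object.__setattr__(self, "strain", s)
        object.__setattr__(self, "g_store", gp)
        object.__setattr__(self, "g_loss", gl)


@dataclass(frozen=True)
class RelaxationTrace:
    """Stress relaxation at constant applied strain: stress (Pa) vs time (s).

    Time starts at zero and increases; the initial stress must be positive so
    the trace can be normalized.
    """

    time: np.ndarray
    stress: np.ndarray
    applied_strain: float = 0.1
    temperature: float = 4.0

    def __post_init__(self) -> None:
        t = _as_1d(self.time, "time")
        s = _as_1d(self.stress, "stress")
        if len(t) != len(s):
            raise ValueError("time and stress must have equal length")
        if len(t) < 8:
            raise ValueError("relaxation trace needs at least 8 points")
        if t[0] != 0:
            raise ValueError("time must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if s[0] <= 0:
            raise ValueError("initial stress must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "stress", s)


@dataclass(frozen=True)
class HBParams:
    """Herschel-Bulkley parameters: sigma = sigma_y + K * gamma_dot ** n_exp."""

    sigma_y: float  # Pa, yield stress (zero-rate intercept of the model)
    K: float  # Pa s^n, consistency
    n_exp: float  # flow index
    rss: float = 0.0  # residual sum of squares of the fit, Pa^2

    def predict(self, shear_rate: np.ndarray) -> np.ndarray:
        gd = np.asarray(shear_rate, dtype=float)
        return self.sigma_y + self.K * gd**self.n_exp


@dataclass(frozen=True)
class StretchedExpFit:
    """Kohlrausch-Williams-Watts fit of a normalized relaxation trace.

    N(t) = residual_frac + (1 - residual_frac) * exp(-(t/tau)**beta)

    ``mean_tau`` is the average relaxation time of the decaying component,
    (tau/beta) * Gamma(1/beta).  ``beta_at_bound`` flags fits where the
    stretching exponent was pinned at its box constraint and should be
    interpreted with caution.
    """

    tau: float  # s
    beta: float  # in (0, 1]
    residual_frac: float  # plateau fraction in [0, 1)
    mean_tau: float  # s
    r2: float
    beta_at_bound: bool = False

    def predict(self, time: np.ndarray) -> np.ndarray:
        t = np.asarray(time, dtype=float)
        return self.residual_frac + (1.0 - self.residual_frac) * np.exp(
            -((t / self.tau) ** self.beta)
        )


@dataclass(frozen=True)
class MicroscopyImage:
    """Grey-level image (or max-projected stack) with a physical pixel scale."""

    pixels: np.ndarray  # 2-D float grey levels
    um_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 3:  # z-stack: reduce by maximum projection
            px = px.max(axis=0)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D image or 3-D stack")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values")
        if not (self.um_per_px > 0):
            raise ValueError("um_per_px must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class LabelMask:
    """Labelled segmentation mask: 0 = background, objects 1..n consecutive."""

    labels: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        present = np.unique(lab[lab > 0])
        if len(present) and not np.array_equal(present, np.arange(1, len(present) + 1)):
            raise ValueError("object labels must be consecutive integers starting at 1")
        if not (self.um_per_px > 0):
            raise ValueError("um_per_px must be positive")
        object.__setattr__(self, "labels", lab)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class OrganoidRecord:
    """Per-object morphometrics in physical units."""

    label: int
    area: float  # um^2
    perimeter: float  # um
    circularity: float  # 4*pi*A/P^2, clipped at 1.05
    centroid: tuple  # (row, col) in px
    crypt_count: int = 0


@dataclass
class TrackedSeries:
    """Per-organoid (time, area, perimeter) trajectories matched across frames.

    ``table`` has columns track, time_s, area_um2, perimeter_um,
    centroid_row, centroid_col with one row per (track, frame) observation.
    """

    table: "object"  # pandas.DataFrame

    def trajectory(self, track: int):
        sub = self.table[self.table["track"] == track]
        return sub.sort_values("time_s").reset_index(drop=True)

    @property
    def track_ids(self) -> np.ndarray:
        return np.unique(self.table["track"].to_numpy())


@dataclass(frozen=True)
class ConditionSample:
    """Per-organoid scalar readouts for one modality x treatment condition."""

    modality: str  # "printed" | "manual"
    treatment: str  # "treated" | "untreated"
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in ("printed", "manual"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.treatment not in ("treated", "untreated"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        v = _as_1d(self.values, "values")
        if np.any(v < 0):
            raise ValueError("readout values must be non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PowerCurve:
    """Bootstrap assay-sensitivity curve: mean p +/- s.e.m. vs per-arm n."""

    n_grid: np.ndarray
    mean_p: np.ndarray
    sem_p: np.ndarray
    iterations: int
    seed: int
    saturated: np.ndarray = field(default=None)  # per-n resampling-saturation flag

    def __post_init__(self) -> None:
        n = np.asarray(self.n_grid, dtype=int)
        mp = _as_1d(self.mean_p, "mean_p")
        sp = _as_1d(self.sem_p, "sem_p")
        if not (len(n) == len(mp) == len(sp)):
            raise ValueError("n_grid, mean_p, sem_p must have equal length")
        if np.any(n < 2):
            raise ValueError("per-arm sample sizes must be >= 2")
        if np.any((mp <= 0) | (mp > 1)):
            raise ValueError("mean p-values must lie in (0, 1]")
        if np.any(sp < 0):
            raise ValueError("s.e.m. must be non-negative")
        sat = self.saturated
        sat = np.zeros(len(n), dtype=bool) if sat is None else np.asarray(sat, bool)
        object.__setattr__(self, "n_grid", n)
        object.__setattr__(self, "mean_p", mp)
        object.__setattr__(self, "sem_p", sp)
        object.__setattr__(self, "saturated", sat)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a two-sample sample-size calculation (Welch t-test)."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.power < 1):
            raise ValueError("power must be in (0, 1)")
        if self.sd_a <= 0 or self.sd_b <= 0:
            raise ValueError("standard deviations must be positive")
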