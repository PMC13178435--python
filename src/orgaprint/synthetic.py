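"""Synthetic-data generators with exact ground truth.

Every input the analysis pipeline consumes can be generated here: flow curves
of a Herschel-Bulkley yield-stress fluid, stretched-exponential stress
relaxation with a residual plateau, amplitude sweeps with a single yielding
crossover, grey-level organoid fields (regular printed grids vs random manual
seeding), lognormal/gamma assay readouts calibrated to a target mean and CV,
and pulsatile tube masks.  Each generator takes an explicit seed, is
bit-reproducible, and returns the ground truth alongside the data so that
downstream fits and segmentations can be scored without external data.

Noise conventions: rheometry noise is multiplicative (instrument noise scales
with signal), image noise is additive Gaussian grey-level noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import (
    AmplitudeSweep,
    ConditionSample,
    FlowCurve,
    HBParams,
    MicroscopyImage,
    RelaxationTrace,
)

__all__ = [
    "RheologySimSpec",
    "ImageSimSpec",
    "AssaySimSpec",
    "ConditionSpec",
    "TubeSimSpec",
    "gen_flow_curve",
    "gen_relaxation_trace",
    "gen_amplitude_sweep",
    "gen_organoid_image",
    "gen_assay_readouts",
    "gen_tube_series",
    "default_assay_spec",
    "lognormal_params",
]


# ---------------------------------------------------------------------------
# Spec containers


@dataclass(frozen=True)
class RheologySimSpec:
    """Ground-truth constitutive parameters for simulated rheometry.

    ``hb`` = (sigma_y Pa, K Pa*s^n, n_exp) Herschel-Bulkley triple;
    ``kww`` = (tau s, beta, residual_frac) stretched-exponential triple;
    ``grid`` holds the sample points (shear rates 1/s for flow curves,
    times s for relaxation traces) and must be strictly increasing;
    ``noise_frac`` is the relative s.d. of multiplicative instrument noise.
    """

    hb: Tuple[float, float, float] = (10.0, 2.0, 0.5)
    kww: Tuple[float, float, float] = (300.0, 0.6, 0.05)
    noise_frac: float = 0.01
    grid: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        sigma_y, K, n_exp = self.hb
        if sigma_y < 0 or K < 0 or n_exp <= 0:
            raise ValueError("require sigma_y >= 0, K >= 0, n_exp > 0")
        tau, beta, resid = self.kww
        if tau <= 0:
            raise ValueError("tau must be positive")
        if not (0 < beta <= 1):
            raise ValueError("beta must lie in (0, 1]")
        if not (0 <= resid < 1):
            raise ValueError("residual fraction must lie in [0, 1)")
        if not (0 <= self.noise_frac < 0.5):
            raise ValueError("noise_frac must lie in [0, 0.5)")
        if self.grid is not None:
            g = np.asarray(self.grid, dtype=float)
            if g.ndim != 1 or len(g) < 2 or np.any(np.diff(g) <= 0):
                raise ValueError("grid must be 1-D and strictly increasing")
            object.__setattr__(self, "grid", g)


@dataclass(frozen=True)
class ImageSimSpec:
    """Layout and optics of a synthetic organoid field.

    ``mode="printed"`` places objects on a regular grid with spacing
    ``pitch_um`` (default 750 um, a typical interorganoid print pitch) and
    draws radii from a truncated normal; ``mode="manual"`` places centroids
    uniformly at random (overlaps allowed, producing fused objects) and draws
    radii from a lognormal with the given CV.  Object boundaries are lobed
    disks r(theta) = R * (1 + lobe_amp * cos(lobes * theta)).
    """

    shape_px: Tuple[int, int] = (1024, 1024)
    um_per_px: float = 2.0
    mode: str = "printed"
    n_organoids: int = 9
    radius_mean_um: float = 100.0
    radius_cv: float = 0.05
    lobes: int = 0
    lobe_amp: float = 0.0
    pitch_um: float = 750.0
    noise_sd: float = 0.02
    blur_sigma_um: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("printed", "manual"):
            raise ValueError("mode must be 'printed' or 'manual'")
        if self.n_organoids < 1:
            raise ValueError("need at least one organoid")
        if self.um_per_px <= 0 or self.radius_mean_um <= 0:
            raise ValueError("scales must be positive")
        if self.radius_cv < 0 or self.noise_sd < 0 or self.blur_sigma_um < 0:
            raise ValueError("dispersions must be non-negative")
        if self.lobes < 0:
            raise ValueError("lobes must be >= 0")
        if not (0 <= self.lobe_amp <= 0.5):
            raise ValueError("lobe_amp must lie in [0, 0.5]")


@dataclass(frozen=True)
class ConditionSpec:
    """Target population mean and CV for one modality x treatment cell."""

    mean: float
    cv: float
    n: int = 200

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.cv <= 0:
            raise ValueError("cv must be positive (cv=0 is a degenerate distribution)")
        if self.n < 2:
            raise ValueError("need n >= 2 per condition")


@dataclass(frozen=True)
class AssaySimSpec:
    """Per-condition readout populations, keyed by (modality, treatment)."""

    conditions: Dict[Tuple[str, str], ConditionSpec]
    family: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gamma"):
            raise ValueError(f"unsupported family {self.family!r}")
        for key in self.conditions:
            modality, treatment = key
            if modality not in ("printed", "manual") or treatment not in (
                "treated",
                "untreated",
            ):
                raise ValueError(f"unknown condition key {key!r}")


@dataclass(frozen=True)
class TubeSimSpec:
    """Pulsatile perfused-tube geometry: width square-waves between
    baseline and baseline*(1+peak_strain) with duty cycle ``duty``."""

    baseline_diam_um: float = 100.0
    peak_strain: float = 0.3
    period_s: float = 20.0
    n_frames: int = 80
    duty: float = 0.5
    frame_interval_s: float = 1.0
    um_per_px: float = 1.0
    tube_length_px: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_strain < 0:
            raise ValueError("peak_strain must be >= 0")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not (0 < self.duty < 1):
            raise ValueError("duty must lie in (0, 1)")
        if self.baseline_diam_um <= 0 or self.period_s <= 0:
            raise ValueError("baseline diameter and period must be positive")


# ---------------------------------------------------------------------------
# Rheometry generators


def gen_flow_curve(
    spec: RheologySimSpec, temperature: float = 4.0
) -> Tuple[FlowCurve, HBParams]:
    """Simulate a unidirectional shear flow curve of a Herschel-Bulkley fluid.

    stress_i = (sigma_y + K * rate_i**n) * (1 + eps_i), eps_i ~ N(0, noise_frac).

    Returns the noisy curve together with the ground-truth parameters.
    """
    rates = spec.grid
    if rates is None:
        rates = np.logspace(-2, 2, 30)
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("shear rates must be strictly positive")
    sigma_y, K, n_exp = spec.hb
    truth = HBParams(sigma_y=sigma_y, K=K, n_exp=n_exp)
    stress = truth.predict(rates)
    if spec.noise_frac > 0:
        rng = np.random.default_rng(spec.seed)
        stress = stress * (1.0 + rng.normal(0.0, spec.noise_frac, size=len(rates)))
    return FlowCurve(shear_rate=rates, stress=stress, temperature=temperature), truth


def gen_relaxation_trace(
    spec: RheologySimSpec,
    sigma0: float,
    duration: float,
    n_points: int = 512,
    applied_strain: float = 0.1,
) -> RelaxationTrace:
    """Simulate stress relaxation with a stretched-exponential decay and plateau.

    sigma(t) = sigma0 * [r + (1-r) * exp(-(t/tau)**beta)] * (1 + noise),
    with the t=0 sample left noiseless so sigma(0) = sigma0 when noise_frac=0.
    The time grid is ``spec.grid`` if provided, else ``n_points`` samples that
    are linear near zero and log-spaced in the tail (relaxation is measured on
    a decaying signal over hours, so uniform sampling wastes the early decade).
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if spec.grid is not None:
        t = np.asarray(spec.grid, dtype=float)
        if t[0] != 0:
            t = np.concatenate([[0.0], t])
    else:
        # linear over the first 1% of the hold, log-spaced beyond
        t_lin = np.linspace(0.0, duration * 0.01, n_points // 4, endpoint=False)
        t_log = np.geomspace(duration * 0.01, duration, n_points - len(t_lin))
        t = np.concatenate([t_lin, t_log])
    tau, beta, resid = spec.kww
    decay = resid + (1.0 - resid) * np.exp(-((t / tau) ** beta))
    stress = sigma0 * decay
    if spec.noise_frac > 0:
        rng = np.random.default_rng(spec.seed)
        eps = rng.normal(0.0, spec.noise_frac, size=len(t))
        eps[0] = 0.0
        stress = stress * (1.0 + eps)
    return RelaxationTrace(
        time=t, stress=stress, applied_strain=applied_strain, temperature=4.0
    )


def gen_amplitude_sweep(
    yield_strain: float,
    G0_store: float,
    G0_loss: float,
    grid: Sequence[float],
    noise_frac: float = 0.0,
    seed: int = 0,
    frequency: float = 1.0,
) -> AmplitudeSweep:
    """Simulate an amplitude sweep with one yielding crossover at ``yield_strain``.

    Functional forms (a minimal smooth model with a single yielding event):

        G''(g) = G0_loss * (1 + x**b) / (1 + x**c),   x = g / yield_strain
        G'(g)  = G0_store / (1 + (g / g1)**a)

    with (a, b, c) = (2, 0.5, 1).  G'' equals G0_loss exactly at the yield
    strain, so g1 is solved from G'(yield_strain) = G0_loss, placing the
    crossover at the requested strain by construction.  Requires the material
    to be solid-like at rest (G0_store > G0_loss).
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or len(g) < 4 or np.any(np.diff(g) <= 0) or np.any(g <= 0):
        raise ValueError("grid must be >= 4 strictly increasing positive strains")
    if not (G0_store > G0_loss):
        raise ValueError(
            "G0_store must exceed G0_loss: a liquid-like material has no "
            "yielding crossover"
        )
    if not (g[0] < yield_strain < g[-1]):
        raise ValueError("grid must bracket the yield strain")
    a, b, c = 2.0, 0.5, 1.0
    x = g / yield_strain
    g_loss = G0_loss * (1.0 + x**b) / (1.0 + x**c)
    # place the crossover: G'(yield_strain) = G0_loss
    g1 = yield_strain / (G0_store / G0_loss - 1.0) ** (1.0 / a)
    g_store = G0_store / (1.0 + (g / g1) ** a)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        g_store = g_store * (1.0 + rng.normal(0.0, noise_frac, size=len(g)))
        g_loss = g_loss * (1.0 + rng.normal(0.0, noise_frac, size=len(g)))
    return AmplitudeSweep(strain=g, g_store=g_store, g_loss=g_loss, frequency=frequency)


# ---------------------------------------------------------------------------
# Imaging generators


def _lobed_disk_mask(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    radius_px: float,
    lobes: int,
    lobe_amp: float,
) -> np.ndarray:
    """Boolean raster of r(theta) = R * (1 + lobe_amp * cos(lobes*theta))."""
    rmax = radius_px * (1.0 + lobe_amp)
    r0 = int(np.floor(center[0] - rmax - 2))
    r1 = int(np.ceil(center[0] + rmax + 3))
    c0 = int(np.floor(center[1] - rmax - 2))
    c1 = int(np.ceil(center[1] + rmax + 3))
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, shape[0]), min(c1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - center[0]
    dx = cc - center[1]
    dist = np.hypot(dy, dx)
    if lobes > 0 and lobe_amp > 0:
        theta = np.arctan2(dy, dx)
        boundary = radius_px * (1.0 + lobe_amp * np.cos(lobes * theta))
    else:
        boundary = radius_px
    patch = dist <= boundary
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = patch
    return mask


def gen_organoid_image(
    spec: ImageSimSpec,
) -> Tuple[MicroscopyImage, pd.DataFrame]:
    """Render a grey-level organoid field plus a ground-truth object table.

    Objects are bright (foreground level 1.0) lobed disks on a dark background,
    Gaussian-blurred by ``blur_sigma_um`` and corrupted with additive Gaussian
    grey-level noise of s.d. ``noise_sd``.  The returned table lists one row
    per object: label, centroid_row, centroid_col (px), radius_um, lobes.

    In printed mode an object whose extent would leave the image raises an
    error; in manual mode overlaps and partial border clipping are allowed,
    mimicking hand-seeded cultures.
    """
    rng = np.random.default_rng(spec.seed)
    rows_px, cols_px = spec.shape_px
    mean_r_px = spec.radius_mean_um / spec.um_per_px

    if spec.mode == "printed":
        side = int(np.ceil(np.sqrt(spec.n_organoids)))
        pitch_px = spec.pitch_um / spec.um_per_px
        span = (side - 1) * pitch_px
        row0 = (rows_px - 1 - span) / 2.0
        col0 = (cols_px - 1 - span) / 2.0
        centers = [
            (row0 + (k // side) * pitch_px, col0 + (k % side) * pitch_px)
            for k in range(spec.n_organoids)
        ]
        # low-dispersion print: truncated-normal radii
        radii_px = rng.normal(mean_r_px, spec.radius_cv * mean_r_px, spec.n_organoids)
        radii_px = np.clip(radii_px, 0.2 * mean_r_px, None)
        for (r, c), rad in zip(centers, radii_px):
            rmax = rad * (1.0 + spec.lobe_amp)
            if r - rmax < 0 or c - rmax < 0 or r + rmax > rows_px - 1 or c + rmax > cols_px - 1:
                raise ValueError(
                    "printed array does not fit in the image: increase shape_px "
                    "or reduce pitch/radius"
                )
    else:  # manual
        centers = [
            (rng.uniform(0, rows_px - 1), rng.uniform(0, cols_px - 1))
            for _ in range(spec.n_organoids)
        ]
        if spec.radius_cv > 0:
            sigma2 = np.log1p(spec.radius_cv**2)
            mu = np.log(mean_r_px) - 0.5 * sigma2
            radii_px = rng.lognormal(mu, np.sqrt(sigma2), spec.n_organoids)
        else:
            radii_px = np.full(spec.n_organoids, mean_r_px)

    field = np.zeros((rows_px, cols_px), dtype=float)
    records = []
    for i, ((r, c), rad) in enumerate(zip(centers, radii_px), start=1):
        field[_lobed_disk_mask((rows_px, cols_px), (r, c), rad, spec.lobes, spec.lobe_amp)] = 1.0
        records.append(
            {
                "label": i,
                "centroid_row": r,
                "centroid_col": c,
                "radius_um": rad * spec.um_per_px,
                "lobes": spec.lobes,
            }
        )
    if spec.blur_sigma_um > 0:
        field = ndimage.gaussian_filter(field, spec.blur_sigma_um / spec.um_per_px)
    if spec.noise_sd > 0:
        field = field + rng.normal(0.0, spec.noise_sd, size=field.shape)
    truth = pd.DataFrame.from_records(records)
    return MicroscopyImage(pixels=field, um_per_px=spec.um_per_px), truth


# ---------------------------------------------------------------------------
# Assay readouts


def lognormal_params(mean: float, cv: float) -> Tuple[float, float]:
    """Log-space (mu, sigma) whose lognormal has exactly this mean and CV.

    mu = ln(mean) - ln(1+cv^2)/2,  sigma^2 = ln(1+cv^2).
    """
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, float(np.sqrt(sigma2))


def gen_assay_readouts(spec: AssaySimSpec) -> Dict[Tuple[str, str], ConditionSample]:
    """Draw per-organoid readouts for every condition in the spec.

    Lognormal parameters are derived so the *population* mean and CV equal the
    spec exactly; the gamma family uses shape 1/cv^2, scale mean*cv^2 (same
    exact moment match).  Conditions are drawn in sorted key order from one
    seeded generator, so the full set is reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    out: Dict[Tuple[str, str], ConditionSample] = {}
    for key in sorted(spec.conditions):
        cond = spec.conditions[key]
        if spec.family == "lognormal":
            mu, sig = lognormal_params(cond.mean, cond.cv)
            values = rng.lognormal(mu, sig, cond.n)
        else:  # gamma
            shape = 1.0 / cond.cv**2
            scale = cond.mean * cond.cv**2
            values = rng.gamma(shape, scale, cond.n)
        out[key] = ConditionSample(modality=key[0], treatment=key[1], values=values)
    return out


def default_assay_spec(
    n_per_condition: int = 200, seed: int = 0, family: str = "lognormal"
) -> AssaySimSpec:
    """Study-condition defaults for the printed-vs-manual sensitivity assay.

    CVs are the four reported coefficients of variation (printed 48%/58%
    treated/untreated; manual 127%/174%) and the treated-untreated mean
    difference is 3.7-fold larger in the printed modality (manual arms at
    mean 1 vs 2 a.u., printed arms at 1 vs 4.7 a.u.).
    """
    conditions = {
        ("printed", "treated"): ConditionSpec(mean=4.7, cv=0.48, n=n_per_condition),
        ("printed", "untreated"): ConditionSpec(mean=1.0, cv=0.58, n=n_per_condition),
        ("manual", "treated"): ConditionSpec(mean=2.0, cv=1.27, n=n_per_condition),
        ("manual", "untreated"): ConditionSpec(mean=1.0, cv=1.74, n=n_per_condition),
    }
    return AssaySimSpec(conditions=conditions, family=family, seed=seed)


# ---------------------------------------------------------------------------
# Perfused-tube series


def gen_tube_series(spec: TubeSimSpec) -> Tuple[np.ndarray, pd.DataFrame]:
    """Render a pulsatile tube as a stack of boolean masks.

    The tube is a horizontal rectangle whose width square-waves between the
    baseline diameter and baseline*(1+peak_strain): frames whose phase within
    the period is below ``duty`` are at peak (flow on).  Returns the mask
    stack (n_frames, rows, cols) and a ground-truth table with columns
    time_s, diameter_um, flow_on.
    """
    times = np.arange(spec.n_frames) * spec.frame_interval_s
    phase = np.mod(times, spec.period_s) / spec.period_s
    flow_on = phase < spec.duty
    diam_um = np.where(
        flow_on,
        spec.baseline_diam_um * (1.0 + spec.peak_strain),
        spec.baseline_diam_um,
    )
    peak_px = int(round(spec.baseline_diam_um * (1.0 + spec.peak_strain) / spec.um_per_px))
    rows = peak_px + 20
    cols = spec.tube_length_px
    mid = rows / 2.0
    stack = np.zeros((spec.n_frames, rows, cols), dtype=bool)
    for k in range(spec.n_frames):
        half = diam_um[k] / spec.um_per_px / 2.0
        rr = np.arange(rows)
        band = (rr >= mid - half) & (rr < mid + half)
        stack[k, band, :] = True
    truth = pd.DataFrame(
        {"time_s": times, "diameter_um": diam_um, "flow_on": flow_on}
    )
    return stack, truth
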