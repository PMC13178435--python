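"""Constitutive-model fitting for yield-stress gels.

Three measurement families are covered:

* flow curves -> Herschel-Bulkley fit, sigma = sigma_y + K * gamma_dot**n.
  The yield stress is the fitted sigma_y parameter, i.e. the model's
  zero-shear-rate intercept.
* amplitude sweeps -> strain (and stress) at the G'/G'' crossover that marks
  yielding, interpolated in log-log space because moduli span decades.
* stress-relaxation traces -> normalization, stretched-exponential (KWW) fit
  with a free residual plateau, average relaxation time
  <tau> = (tau/beta) * Gamma(1/beta), fraction relaxed and residual stress.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import optimize
from scipy.special import gamma as gamma_fn

from .datatypes import (
    AmplitudeSweep,
    FlowCurve,
    HBParams,
    RelaxationTrace,
    StretchedExpFit,
)

__all__ = [
    "fit_herschel_bulkley",
    "crossover_strain",
    "normalize_relaxation",
    "fit_stretched_exponential",
    "fraction_relaxed",
    "residual_stress",
    "FitError",
]


class FitError(RuntimeError):
    """A nonlinear fit failed to converge after bounded restarts."""


_K_FLOOR = 1e-12  # Pa s^n; K is reported at this bound for plug-like data


def _hb_model(gd: np.ndarray, sigma_y: float, K: float, n_exp: float) -> np.ndarray:
    return sigma_y + K * gd**n_exp


def fit_herschel_bulkley(curve: FlowCurve) -> HBParams:
    """Fit sigma = sigma_y + K * gamma_dot**n by bounded least squares.

    Fitting is done in linear stress space with multi-start over the flow
    index n in {0.2, 0.5, 0.8, 1.2}; the restart with the lowest residual sum
    of squares wins.  For plug-like data (constant stress) K collapses to its
    lower bound and sigma_y carries the plateau.

    Raises
    ------
    FitError
        If no restart converges.
    """
    gd = curve.shear_rate
    st = curve.stress
    span = max(st.max() - st.min(), 0.0)
    best: Tuple[float, np.ndarray] | None = None
    for n0 in (0.2, 0.5, 0.8, 1.2):
        # intercept guess from the low-rate end, consistency from the span
        sigma0 = max(st[0], 1e-9)
        K0 = max(span / max(gd[-1] ** n0, 1e-12), _K_FLOOR * 10)
        try:
            popt, _ = optimize.curve_fit(
                _hb_model,
                gd,
                st,
                p0=(sigma0, K0, n0),
                bounds=([0.0, _K_FLOOR, 1e-3], [np.inf, np.inf, 5.0]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((st - _hb_model(gd, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise FitError(
            "Herschel-Bulkley fit did not converge from any restart "
            f"(n points={len(gd)}, stress range {st.min():.3g}-{st.max():.3g} Pa)"
        )
    rss, (sigma_y, K, n_exp) = best
    return HBParams(sigma_y=float(sigma_y), K=float(K), n_exp=float(n_exp), rss=rss)


def crossover_strain(sweep: AmplitudeSweep) -> Tuple[float, float]:
    """Strain and stress at the first G' = G'' crossover of an amplitude sweep.

    The material must be solid-like at the lowest strain (G' > G'').  The
    crossover is located by linear interpolation in log-log coordinates
    between the bracketing samples; the crossover stress is the interpolated
    modulus times the crossover strain.

    Raises
    ------
    ValueError
        If G' <= G'' at the lowest strain, or no sign change exists anywhere
        ("no yielding detected").
    """
    diff = sweep.g_store - sweep.g_loss
    if diff[0] <= 0:
        raise ValueError("material is not solid-like at the lowest strain (G' <= G'')")
    sign_change = np.nonzero((diff[:-1] > 0) & (diff[1:] <= 0))[0]
    if len(sign_change) == 0:
        raise ValueError("no yielding detected: G' and G'' never cross")
    i = int(sign_change[0])
    x0, x1 = np.log(sweep.strain[i]), np.log(sweep.strain[i + 1])
    ls0, ls1 = np.log(sweep.g_store[i]), np.log(sweep.g_store[i + 1])
    ll0, ll1 = np.log(sweep.g_loss[i]), np.log(sweep.g_loss[i + 1])
    # intersection of the two log-log chords
    slope_s = (ls1 - ls0) / (x1 - x0)
    slope_l = (ll1 - ll0) / (x1 - x0)
    if slope_s == slope_l:  # parallel chords: crossover at the right sample
        x_star = x1
    else:
        x_star = x0 + (ll0 - ls0) / (slope_s - slope_l)
    x_star = min(max(x_star, x0), x1)
    g_star = float(np.exp(x_star))
    modulus = float(np.exp(ls0 + slope_s * (x_star - x0)))
    return g_star, modulus * g_star


def normalize_relaxation(trace: RelaxationTrace) -> RelaxationTrace:
    """Divide the stress channel by its initial value; times unchanged."""
    s0 = trace.stress[0]
    if s0 <= 0:
        raise ValueError("initial stress must be positive to normalize")
    return RelaxationTrace(
        time=trace.time,
        stress=trace.stress / s0,
        applied_strain=trace.applied_strain,
        temperature=trace.temperature,
    )


def _resample_log(trace: RelaxationTrace, n: int = 120) -> Tuple[np.ndarray, np.ndarray]:
    """Interpolate a normalized trace onto log-spaced times (t=0 kept).

    Hour-long holds at a fixed sampling rate are >99% tail; log-spacing keeps
    the early decay from being swamped in the least-squares objective.
    """
    t = trace.time
    s = trace.stress
    t_pos = t[t > 0]
    grid = np.geomspace(t_pos[0], t[-1], n - 1)
    s_grid = np.interp(grid, t, s)
    return np.concatenate([[0.0], grid]), np.concatenate([[s[0]], s_grid])


def _kww(t: np.ndarray, tau: float, beta: float, resid: float) -> np.ndarray:
    return resid + (1.0 - resid) * np.exp(-((t / tau) ** beta))


def fit_stretched_exponential(trace: RelaxationTrace) -> StretchedExpFit:
    """Fit N(t) = r + (1-r) exp(-(t/tau)^beta) to a relaxation trace.

    The trace is normalized by its initial stress and resampled onto
    log-spaced times before fitting.  The average relaxation time of the
    decaying component is <tau> = (tau/beta) * Gamma(1/beta); the residual
    plateau r is a free parameter in [0, 1).  beta is constrained to (0, 1];
    a fit pinned at the beta bounds is flagged, not rejected.

    Requires at least 8 points spanning a decade of time after t=0.
    """
    t_pos = trace.time[trace.time > 0]
    if len(t_pos) < 7 or t_pos[-1] / t_pos[0] < 10:
        raise ValueError("need >= 8 points spanning at least a decade of time")
    norm = normalize_relaxation(trace)
    t_fit, s_fit = _resample_log(norm)

    # initial guesses: plateau from the tail, tau from the 1/e crossing
    resid0 = float(np.clip(np.median(s_fit[-5:]), 0.0, 0.95))
    target = resid0 + (1.0 - resid0) / np.e
    below = np.nonzero(s_fit <= target)[0]
    tau0 = float(t_fit[below[0]]) if len(below) else float(t_fit[-1])
    tau0 = max(tau0, t_pos[0])
    best = None
    for beta0 in (0.4, 0.7, 1.0):
        try:
            popt, _ = optimize.curve_fit(
                _kww,
                t_fit,
                s_fit,
                p0=(tau0, beta0, resid0),
                bounds=([1e-9, 1e-3, 0.0], [np.inf, 1.0, 1.0 - 1e-9]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((s_fit - _kww(t_fit, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise FitError("stretched-exponential fit did not converge from any restart")
    rss, (tau, beta, resid) = best
    sst = float(np.sum((s_fit - s_fit.mean()) ** 2))
    r2 = 1.0 - rss / sst if sst > 0 else 1.0
    mean_tau = (tau / beta) * gamma_fn(1.0 / beta)
    at_bound = bool(beta >= 1.0 - 1e-3 or beta <= 2e-3)
    return StretchedExpFit(
        tau=float(tau),
        beta=float(beta),
        residual_frac=float(resid),
        mean_tau=float(mean_tau),
        r2=float(r2),
        beta_at_bound=at_bound,
    )


def fraction_relaxed(trace: RelaxationTrace, at_time: float) -> float:
    """1 - N(at_time): the fraction of the initial stress dissipated by then.

    N is the normalized trace, linearly interpolated between samples.
    """
    if not (trace.time[0] <= at_time <= trace.time[-1]):
        raise ValueError(
            f"at_time={at_time} outside trace range "
            f"[{trace.time[0]}, {trace.time[-1]}] s"
        )
    norm = normalize_relaxation(trace)
    return float(1.0 - np.interp(at_time, norm.time, norm.stress))


def residual_stress(trace: RelaxationTrace) -> float:
    """Mean of the final 5% of raw stress samples (Pa) — the unrelaxed plateau."""
    n_tail = max(1, int(np.ceil(0.05 * len(trace.stress))))
    return float(np.mean(trace.stress[-n_tail:]))
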