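"""Assay-sensitivity statistics for printed vs manually seeded organoid arrays.

The question these tools answer: how many per-organoid comparisons does an
assay need before a treatment effect reaches significance, and how does that
number depend on the dispersion of the culture?  Components:

* coefficient of variation (sample s.d. / mean),
* a two-sided Mann-Whitney U test — exact permutation distribution for small
  tie-free comparisons, tie- and continuity-corrected normal approximation
  otherwise — with a vectorized core so thousands of bootstrap tests are cheap,
* the D'Agostino-Pearson K^2 normality test,
* the bootstrap p-vs-n sensitivity curve (mean +/- s.e.m. of p over repeated
  size-n resampled comparisons; 512 iterations by default) and extraction of
  the smallest n whose mean p clears a significance level,
* post-hoc per-group sample size for a two-sided Welch t-test by
  noncentral-t iteration.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import ConditionSample, PowerCurve, PowerSpec

__all__ = [
    "coefficient_of_variation",
    "mann_whitney_p",
    "dagostino_pearson",
    "bootstrap_power_curve",
    "min_n_below_alpha",
    "required_sample_size",
    "effect_summary",
]

_EXACT_MAX_N = 8  # exact permutation distribution up to 8-vs-8


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV: standard deviation (n-1 denominator) over the mean."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D sample of at least 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U: counts[u] = #assignments of n1-of-(n1+n2) ranks
    with Mann-Whitney statistic u.  Tie-free recurrence
    N(n1, n2, u) = N(n1-1, n2, u-n2) + N(n1, n2-1, u)."""
    if n1 == 0 or n2 == 0:
        c = np.zeros(n1 * n2 + 1)
        c[0] = 1.0
        return c
    c = np.zeros(n1 * n2 + 1)
    c1 = _u_counts(n1 - 1, n2)  # largest pooled value in group 1: U gains n2
    c[n2 : n2 + len(c1)] += c1
    c2 = _u_counts(n1, n2 - 1)
    c[: len(c2)] += c2
    return c


def _exact_two_sided_p(u: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Two-sided exact p = 2 * min(P(U <= u), P(U >= u)), capped at 1."""
    counts = _u_counts(n1, n2)
    cdf = np.cumsum(counts) / counts.sum()
    sf_incl = 1.0 - np.concatenate([[0.0], cdf[:-1]])  # P(U >= u), point included
    u_idx = np.rint(u).astype(int)
    p = 2.0 * np.minimum(cdf[u_idx], sf_incl[u_idx])
    return np.minimum(p, 1.0)


def _batch_mannwhitney(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney p for each row of paired sample matrices.

    a: (m, n1), b: (m, n2).  Rows with n1, n2 <= 8 and no between-group tied
    values use the exact permutation distribution; all other rows use the
    normal approximation with tie and continuity corrections.  Duplicated
    values *within* one group (as arise from bootstrap resampling) are treated
    as distinct observations and do not disqualify a row from the exact path.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    m, n1 = a.shape
    n2 = b.shape[1]
    n = n1 + n2
    pooled = np.concatenate([a, b], axis=1)
    ranks = stats.rankdata(pooled, axis=1, method="average")
    u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0

    # tie structure from the sorted pooled rows
    order = np.argsort(pooled, axis=1, kind="stable")
    s = np.take_along_axis(pooled, order, axis=1)
    grp = np.where(order < n1, 0, 1)
    eq = s[:, 1:] == s[:, :-1]
    cross_tie = np.any(eq & (grp[:, 1:] != grp[:, :-1]), axis=1)

    # sum over tie runs of (t^3 - t), vectorized via position-in-run
    starts = np.concatenate([np.ones((m, 1), dtype=bool), ~eq], axis=1)
    idx = np.broadcast_to(np.arange(n), (m, n))
    start_idx = np.maximum.accumulate(np.where(starts, idx, -1), axis=1)
    pos = idx - start_idx  # 0-based position within the tie run
    # sum(t^3 - t) over runs == sum over elements of 6*C(pos,1)+... use
    # t^3 - t = 6*C(t,2) + 6*C(t,3); pairs = sum(pos), triples = sum(C(pos,2))
    pairs = pos.sum(axis=1)
    triples = (pos * (pos - 1) // 2).sum(axis=1)
    tie_term = 6.0 * pairs + 6.0 * triples

    mean_u = n1 * n2 / 2.0
    var_u = n1 * n2 / 12.0 * ((n + 1.0) - tie_term / (n * (n - 1.0)))
    sd_u = np.sqrt(np.maximum(var_u, 0.0))
    num = np.maximum(np.abs(u1 - mean_u) - 0.5, 0.0)  # continuity correction
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_u > 0, num / sd_u, 0.0)
    p = special.erfc(z / np.sqrt(2.0))  # two-sided
    p = np.minimum(p, 1.0)

    if n1 <= _EXACT_MAX_N and n2 <= _EXACT_MAX_N:
        exact_rows = ~cross_tie
        if exact_rows.any():
            p[exact_rows] = _exact_two_sided_p(u1[exact_rows], n1, n2)
    return p


def mann_whitney_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value (the 'non-parametric t-test' of assay reports).

    Exact permutation p for n_a, n_b <= 8 with no between-group ties; normal
    approximation with tie and continuity corrections otherwise.  Two
    identical samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise ValueError("need two 1-D samples with at least 2 values each")
    return float(_batch_mannwhitney(a[None, :], b[None, :])[0])


def dagostino_pearson(values: Sequence[float]) -> Tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test (K^2 statistic, p).

    K^2 combines the normalized skewness and kurtosis z-scores and is referred
    to a chi-square with 2 d.f.; the transformations are only calibrated for
    n >= 20, so smaller samples are rejected.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("need a 1-D sample")
    if len(v) < 20:
        raise ValueError(f"D'Agostino-Pearson requires n >= 20, got {len(v)}")
    k2, p = stats.normaltest(v)
    return float(k2), float(p)


# ---------------------------------------------------------------------------
# Bootstrap sensitivity curve


def bootstrap_power_curve(
    treated: Sequence[float],
    untreated: Sequence[float],
    n_grid: Sequence[int],
    iterations: int = 512,
    seed: int = 0,
    replace: bool = True,
) -> PowerCurve:
    """Mean +/- s.e.m. of the Mann-Whitney p over repeated size-n comparisons.

    For each per-arm size n in ``n_grid``, draw n treated and n untreated
    values (with replacement by default; ``replace=False`` subsamples without
    replacement, requiring n <= the sample size), test the two draws, and
    repeat ``iterations`` times.  Grid entries above 10x the smaller sample
    are flagged as resampling-saturated in the returned curve, not rejected.
    """
    a = np.asarray(treated, dtype=float)
    b = np.asarray(untreated, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n_grid = np.asarray(n_grid, dtype=int)
    rng = np.random.default_rng(seed)
    mean_p = np.empty(len(n_grid))
    sem_p = np.empty(len(n_grid))
    saturated = n_grid > 10 * min(len(a), len(b))
    for i, n in enumerate(n_grid):
        if replace:
            ia = rng.integers(0, len(a), size=(iterations, n))
            ib = rng.integers(0, len(b), size=(iterations, n))
        else:
            if n > len(a) or n > len(b):
                raise ValueError(
                    f"cannot subsample n={n} without replacement from samples "
                    f"of size {len(a)} and {len(b)}"
                )
            ia = np.argsort(rng.random((iterations, len(a))), axis=1)[:, :n]
            ib = np.argsort(rng.random((iterations, len(b))), axis=1)[:, :n]
        p = _batch_mannwhitney(a[ia], b[ib])
        mean_p[i] = p.mean()
        sem_p[i] = p.std(ddof=1) / np.sqrt(iterations) if iterations > 1 else 0.0
    return PowerCurve(
        n_grid=n_grid,
        mean_p=mean_p,
        sem_p=sem_p,
        iterations=iterations,
        seed=seed,
        saturated=saturated,
    )


def min_n_below_alpha(curve: PowerCurve, alpha: float) -> Optional[int]:
    """Smallest per-arm n whose mean bootstrap p falls below alpha.

    Returns None when the curve never crosses alpha ("not reached").
    """
    below = np.nonzero(curve.mean_p < alpha)[0]
    if len(below) == 0:
        return None
    return int(curve.n_grid[below[0]])


# ---------------------------------------------------------------------------
# Sample-size calculation


def _welch_power(n: int, spec: PowerSpec) -> float:
    """Power of a two-sided Welch t-test with n per group, by noncentral t."""
    va = spec.sd_a**2 / n
    vb = spec.sd_b**2 / n
    se = np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n - 1) + vb**2 / (n - 1))
    ncp = abs(spec.mean_a - spec.mean_b) / se
    t_crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(
        stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    )


def required_sample_size(spec: PowerSpec) -> int:
    """Smallest per-group n giving a two-sided Welch t-test power >= spec.power.

    Found by doubling then bisecting on the noncentral-t power function.
    The Welch (unequal-variance) form is used because the two arms of the
    assay have strongly unequal CVs.  A zero effect is unachievable.
    """
    if spec.mean_a == spec.mean_b:
        raise ValueError("zero effect: required sample size unachievable")
    lo = 2
    if _welch_power(lo, spec) >= spec.power:
        return lo
    hi = 4
    while _welch_power(hi, spec) < spec.power:
        hi *= 2
        if hi > 10_000_000:
            raise ValueError("required sample size exceeds 1e7; effect too small")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _welch_power(mid, spec) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi


def effect_summary(
    samples: Dict[Tuple[str, str], ConditionSample]
) -> Dict[str, object]:
    """Per-condition mean/CV/n plus the between-modality effect-size ratio.

    Requires all four modality x treatment cells.  Reports
    delta_modality = mean(treated) - mean(untreated) for each modality and
    the ratio delta_printed / delta_manual (None when delta_manual == 0,
    flagged as undefined).
    """
    required = [
        ("printed", "treated"),
        ("printed", "untreated"),
        ("manual", "treated"),
        ("manual", "untreated"),
    ]
    for key in required:
        if key not in samples:
            raise ValueError(f"missing condition {key!r}")
    rows = []
    for key in required:
        v = samples[key].values
        rows.append(
            {
                "modality": key[0],
                "treatment": key[1],
                "n": len(v),
                "mean": float(v.mean()),
                "cv": coefficient_of_variation(v),
            }
        )
    table = pd.DataFrame(rows)
    deltas = {}
    for modality in ("printed", "manual"):
        deltas[modality] = float(
            samples[(modality, "treated")].values.mean()
            - samples[(modality, "untreated")].values.mean()
        )
    ratio: Optional[float] = None
    if deltas["manual"] != 0:
        ratio = deltas["printed"] / deltas["manual"]
    return {
        "table": table,
        "delta_printed": deltas["printed"],
        "delta_manual": deltas["manual"],
        "delta_ratio": ratio,
        "ratio_defined": ratio is not None,
    }
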