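# Methods

This note documents the models, parameter choices and numerical decisions
behind each module, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Rheology

**Herschel–Bulkley fitting.** Flow curves are fit in linear stress space to
σ(γ̇) = σ_y + K·γ̇ⁿ with bounds σ_y ≥ 0, K > 0, n ∈ (0.001, 5), using
Levenberg–Marquardt/trust-region least squares with multi-start over
n₀ ∈ {0.2, 0.5, 0.8, 1.2}; the restart with the lowest residual sum of
squares wins. Multi-start matters because the (K, n) pair is weakly
identified when data span few decades of shear rate. The yield stress is
reported as the fitted σ_y parameter — the model's zero-rate intercept — not
as a graphical extrapolation of the data. For plug-like (constant-stress)
data K collapses to its lower bound (10⁻¹² Pa·sⁿ) and σ_y carries the
plateau; this is reported, not treated as an error. Fitting in linear rather
than log stress space weights the high-stress points more; with
multiplicative instrument noise this slightly favours the large-rate region,
which is where K and n are determined, while σ_y is pinned by the low-rate
plateau. The Monte-Carlo recovery suite (200 curves, 1% multiplicative
noise, 30 points over 4 decades) shows a median yield-stress error well
under 1%, far inside the 5% budget asserted in the tests.

**Amplitude-sweep crossover.** The yield strain is the first strain at which
G′ − G″ changes sign. Both moduli span decades, so the crossover is located
by intersecting the two chords in (log γ, log G) space between the
bracketing samples; the crossover stress is the interpolated modulus times
the crossover strain. A material with G′ ≤ G″ at the lowest strain, or with
no sign change at all, raises a "no yielding detected" error rather than
returning a fabricated value — amplitude sweeps of dilute suspensions
genuinely lack a crossover.

**Stretched-exponential relaxation.** Traces are normalized by their initial
stress and fit to N(t) = r + (1 − r)·exp(−(t/τ)^β) with r ∈ [0, 1) free,
β ∈ (0, 1], τ > 0. The plateau sits *outside* the stretched exponential:
N(∞) = r, so the reported fraction relaxed (1 − N) and residual stress are
consistent with the same parameter set. This plateau-outside convention is a
choice among parameterizations that the literature does not settle; it is
flagged here and in the fit metadata. The average relaxation time
⟨τ⟩ = (τ/β)·Γ(1/β) is the mean of the decaying component only — the plateau,
which never relaxes, is deliberately excluded from the average. Before
fitting, the trace is resampled onto ~120 log-spaced time points (keeping
t = 0): an hour-long hold sampled uniformly is >99% tail, and without
resampling the least-squares objective would ignore the early decay that
determines β. Fits with β pinned at a bound (within 10⁻³) are flagged
`beta_at_bound`; a true single exponential legitimately pins β = 1, so the
flag is a caution, not a failure. Residual stress is the mean of the final
5% of raw samples, which assumes the hold is long enough for the tail to
reach its plateau (t_end ≳ 5τ); for slower-relaxing materials the number
reported is an upper bound on the true plateau.

## Synthetic data

The generators reproduce the *statistical and geometric structure* the
analyses assume — not the physics of gels or tissues. All take explicit
integer seeds, use `numpy.random.default_rng`, and are bit-reproducible.

* **Rheometry noise is multiplicative** (relative s.d. `noise_frac`, default
  1%): instrument noise on stress scales with signal across the decades a
  flow curve spans. The t = 0 sample of relaxation traces is left noiseless
  so normalization is exact.
* **Amplitude sweeps** use G″(γ) = G₀″(1 + x^0.5)/(1 + x), x = γ/γ_y — a
  loss modulus with the characteristic yielding overshoot that returns to
  G₀″ exactly at the yield strain — and G′(γ) = G₀′/(1 + (γ/γ₁)²) with γ₁
  solved so G′(γ_y) = G₀″. The crossover therefore sits at the requested
  strain by construction. The crossing is unique provided G₀′/G₀″ ≳ 1.3
  (below that, the G″ overshoot, which peaks at ≈1.21·G₀″, can graze G′);
  solid-like gels are comfortably above this.
* **Organoid fields** are lobed disks r(θ) = R(1 + a·cos kθ) rasterized at
  foreground level 1.0, Gaussian-blurred, with additive Gaussian grey-level
  noise. Printed mode places centroids on a regular grid (default pitch
  750 µm, a typical interorganoid print spacing) with truncated-normal radii;
  manual mode places centroids uniformly at random — overlaps are allowed
  and produce fused objects, as in hand-seeded cultures — with lognormal
  radii. What the generator does *not* emulate: intensity texture inside
  organoids, uneven illumination, debris, or z-blur; segmentation results on
  these images bound what the recipe can do under the stated SNR, not what
  it will do on arbitrary microscopy.
* **Assay readouts** are lognormal (default) or gamma, with parameters
  derived so the *population* mean and CV match the request exactly
  (lognormal: µ_log = ln m − ½ln(1+cv²), σ²_log = ln(1+cv²)). The default
  study conditions put the four modality × treatment cells at CVs of
  48%/58% (printed treated/untreated) and 127%/174% (manual), with the
  treated−untreated mean difference 3.7× larger in the printed modality
  (manual means 1 vs 2 a.u., printed 1 vs 4.7 a.u.). The default 200
  organoids per condition reflects a plausible high-throughput imaging
  experiment; sample CVs of the cv = 1.74 cell converge slowly (the
  lognormal fourth moment is large), so population-level checks use 10⁵
  draws. Lognormal is the default family because fluorescence volumes are
  non-negative and the manual condition is strongly non-normal.
* **Tubes** are horizontal rectangles whose width square-waves between the
  baseline diameter and baseline·(1 + peak strain), default 30% peak strain,
  matching pulsatile perfusion at the pressures of interest. Rasterization
  quantizes the width to 1 px, which bounds the recoverable strain accuracy.

## Morphometrics

**Segmentation** is blur (default σ = 10 µm, the midpoint of the 5–20 µm
range used in practice) → adaptive local-mean threshold over a square window
of 400 µm (≈2× a typical organoid diameter) → hole filling → 8-connected
components → exact size filter (default 5,000 µm²) → optional border
exclusion. Two additions to the plain recipe proved necessary. First, the
local-mean threshold alone lets zero-mean background noise percolate: half
of any flat background sits above its own local mean, and after blurring
those pixels form connected regions far larger than the size filter. A
global floor at half the Otsu threshold suppresses this without touching
real objects. Second, the local-mean boundary sits well below the mid-edge
intensity (the window average mixes mostly background), biasing object areas
up by ~15–20% at these object/window ratios; each detected object is
therefore re-thresholded at the midpoint between its plateau median and the
surrounding background median. Because Gaussian blur is symmetric, the
half-max contour coincides with the true boundary, and measured disk areas
land within ~1% of truth. Blank images yield an empty mask, not an error.

**Perimeter.** No pixel-count estimator is accurate for both smooth and
polygonal outlines (Crofton-style estimators undercount axis-aligned
squares by ~5%; ImageJ-style weighted counts overcount smooth disks by
~5%). Perimeters are therefore measured as the length of the
marching-squares 0.5-level contour after a 5-point circular moving-average
smoothing, which lands within ~0.5% for a R = 100 px disk, ~1% for a square,
and tracks the analytic boundary integral of lobed shapes. Circularity
4πA/P² is clipped at 1.05 to absorb residual rasterization overshoot on
small objects.

**Crypt counting** is an original radial-profile peak counter, not a
reimplementation of any published crypt-analysis tool: the boundary is
expressed as r(θ) over 360 one-degree bins (outer boundary: maximum radius
per bin), circularly smoothed over 9°, and peaks are counted with prominence
≥ 5% of the median radius and separation ≥ 20°. On synthetic k-lobed
boundaries it returns exactly k for lobe amplitudes ≥ 0.15 (k ≤ 7,
R = 100 px) and 0 below the prominence threshold; that operating region is
asserted in the tests, and nothing outside it is claimed. Real crypts are
less sinusoidal than the benchmark; counts on real masks should be
validated against annotation before being trusted.

**Tracking** is greedy nearest-centroid linking with a gate of half the mean
object diameter per frame interval (printed arrays barely move between
frames); ambiguous equal-distance matches are resolved lowest-previous-label
first, a documented tie-break rather than a hidden one. Merges terminate one
trajectory rather than being resolved. **Perimeter strain** is the fractional
perimeter change over non-overlapping windows laid from each trajectory's
start, with perimeters linearly interpolated at window edges. **Tube
diameter** is thresholded area divided by the extent along the tube axis;
the strain baseline is the mean diameter over flagged no-flow frames (or,
absent flags, frames below the min/max midpoint).

## Assay statistics

"Non-parametric t-test" is implemented as the two-sided Mann–Whitney U test
— the only standard reading. For n₁, n₂ ≤ 8 with no between-group ties the
p-value comes from the exact permutation distribution of U (tie-free
recurrence); otherwise from the normal approximation with tie and continuity
corrections. Duplicated values *within* one arm — which bootstrap resampling
produces by construction — are treated as distinct observations and do not
disqualify a comparison from the exact path; ties *between* arms do. Two
identical samples return p = 1.

**Bootstrap sensitivity curves** draw n values per arm with replacement
(subsampling without replacement is available behind a flag; no pairing is
imposed, since treated and untreated organoids are physically distinct),
apply the Mann–Whitney test, and report the mean and s.e.m. of p over 512
iterations per n, vectorized so full curves cost well under a second. The
*mean* of p (not the median) defines the curve, matching the mean ± s.e.m.
convention of sensitivity plots. Grid entries beyond 10× the smaller sample
are flagged as resampling-saturated but still computed. One discreteness
caveat: for per-arm n ≤ 3 the exact two-sided p takes so few values that its
*null* expectation exceeds 0.5 (exactly 0.62 at 3 vs 3), so null-calibration
checks start at n = 4; this is a property of the exact test, not an
artefact.

**Sample size** uses the two-sided Welch t-test (the two arms have strongly
unequal CVs): the smallest integer n per group whose noncentral-t power
reaches the target (default α = 0.05, power = 0.8), found by doubling and
bisection. With equal variances this reproduces the classical values
(n = 17 per group at d = 1, n = 64 at d = 0.5) and stays within +2 of the
normal-approximation closed form 2(z_{1−α/2}+z_{1−β})²/d² across
d ∈ [0.3, 1.5].

## Problem sizes and runtimes

The default benchmark sizes — 200 Monte-Carlo flow curves, 512 bootstrap
iterations, 100 replicates of the printed-vs-manual comparison on 200
organoids per condition, 900²-px images — were chosen so the full test suite
runs in about a minute on one CPU while keeping Monte-Carlo error far below
every asserted tolerance. The reproduction script
(`scripts/acceptance.py`) uses 10⁵ draws per condition for population-CV
estimates because the cv = 1.74 lognormal cell needs them.

## Known limitations

* The KWW plateau convention (outside the normalized exponential) and the
  with-replacement unpaired bootstrap are documented choices among
  defensible alternatives; both alternatives are either exposed as options
  or trivially derived.
* The adaptive-threshold recipe is validated only on the synthetic image
  family described above; cross-tool agreement with any specific Fiji plugin
  cannot be asserted because such plugins' parameters vary.
* The crypt counter is a geometric stand-in validated on synthetic ground
  truth only.
* Exact Mann–Whitney p-values with between-group ties fall back to the
  corrected normal approximation even at small n, where it is only
  approximate.
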