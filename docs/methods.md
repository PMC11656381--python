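# Methods

This note documents the models, algorithms, parameter choices, and
numerical decisions behind `specdecon`, and what the synthetic test
suites do and do not demonstrate.

## Signal model and pipeline order

A spectrum is a pair of vectors (x, y), x strictly increasing, both
finite. The analysis assumes y is a sum of unimodal line-shape
components plus a slowly varying additive baseline plus noise. The
pipeline order — interpolate, denoise, detrend, detect, decompose — is
fixed: detection needs a uniform grid (for finite differences) and a
flat baseline (so amplitude filters are meaningful), and decomposition
needs detected peaks for its initialization. Requesting a later stage
without the earlier ones is rejected rather than reordered.

## Preprocessing

**Interpolation** is linear onto `n_interp` equally spaced points.
Linear (not spline) is deliberate: splines overshoot near sharp
features and the overshoot produces spurious curvature extrema that the
detector downstream would report as candidates. Endpoints are preserved
exactly.

**Denoising** is a centered moving average ("boxcar") of `window`
samples, truncated at the array edges; even windows take the extra
sample on the left. Multiple passes with decreasing windows
(e.g. 100, 30, 10) approximate a Gaussian kernel while keeping a single
intuitive parameter. The boxcar preserves total mass away from the
edges and never widens the amplitude range. It is a poor derivative
estimator at low signal-to-noise, which matters for detection (below).

## Baseline correction

The penalized-least-squares (Whittaker-smoother) baseline minimizes

    S(z) = Σᵢ wᵢ (sᵢ − zᵢ)² + λ ‖D z‖²,

with D the (n−2)×n second-difference matrix. The stationary condition
is the pentadiagonal system (W + λDᵀD) z = W s, solved sparsely.

*Numerical note.* The affine part of the solution lies in D's null
space and is transported through a system whose conditioning degrades
linearly in λ. The solver therefore first computes the weighted affine
fit a(x) (a 2-column least squares), then solves for the deviation:
z = a + (W+λDᵀD)⁻¹W(s−a). This is algebraically identical but keeps
the right-hand side at residual scale, so the λ→∞ limit (the weighted
least-squares straight line) is reached to ~1e−9 instead of ~1e−4 at
λ = 1e12, n = 100.

**airPLS** re-estimates weights each iteration t as wᵢ = 0 where
sᵢ ≥ zᵢ and wᵢ = exp(t·|dᵢ|/‖d‖₁) where sᵢ < zᵢ, with d the negative
part of s − z; the two endpoint weights are anchored to the largest
such weight so the baseline cannot drift free at the edges. Iteration
stops when ‖d‖₁ < ratio·‖s‖₁.

**arPLS** computes the mean μ and standard deviation σ of the negative
residuals and sets logistic weights

    wᵢ = 1 / (1 + exp( 2(dᵢ − (2σ − μ)) / σ )),

a *non-increasing* function of dᵢ = sᵢ − zᵢ: points rising above the
baseline (peaks) get weight ≈ 0 and are excluded from the fit, points
at or below it get weight ≈ 1. This orientation is what makes the
detrended signal come out primarily positive. Iteration stops when the
relative change of the weight vector drops below `ratio`, or
degenerately (converged) when no residual is negative or σ falls to
floating-point noise relative to the signal scale — which happens
exactly for affine inputs, where the smoother is a fixed point.

Both methods clip exponent arguments at ±500 so weights saturate
instead of overflowing, start from all-ones weights, and share the
single `ratio` knob (default 1e−6) and `lam` (default 200; useful
values scale roughly with the fourth power of the feature width *in
samples*, so fine grids need much larger λ).

**Limits of detrending.** A penalized baseline stiff enough to spare a
feature cannot follow drift on the same scale. For broad, strongly
overlapping bands (UV–vis-like) the composite envelope has the same
scale as any plausible drift; detrending then eats the bands, and the
recommended treatment for that regime is no detrending at all (the
`broad_uvvis` suite's settings reflect this). The arPLS positivity
property still holds there — it is a property of the weight scheme, not
of whether detrending is advisable.

## Peak detection

Candidates are indices where −y″ (central second differences; endpoint
values copied from the nearest interior point) has a local maximum with
positive curvature. Two tie-breaks extend the strict definition:

* plateaus of equal −y″ flanked by smaller values count as one
  candidate at the plateau midpoint — a symmetric peak whose apex falls
  exactly midway between grid points produces a two-sample plateau and
  would otherwise vanish;
* curvature must exceed 1e−9·max|y|/h², the rounding-noise floor of
  the stencil, or flat and affine stretches sprout candidates from
  floating-point jitter.

A window of `window_size` samples then slides along the grid with step
one (truncated, not skipped, at the edges). Per placement, the
candidate with the largest intensity wins (intensity ties break toward
the smaller index) and is accepted if the in-window amplitude range
max−min reaches `threshold` and the peak's own intensity reaches
`min_amplitude`; accepted indices are deduplicated. A window on the
order of the expected FWHM in samples works well: much smaller windows
sit on peak tops where the local range is tiny, much larger ones force
nearby peaks to compete.

The count of accepted peaks is non-increasing in `threshold` and
`min_amplitude` by construction. In `window_size` it is non-increasing
over the operating regime where every true peak's in-window range
already saturates at the smallest window considered; for thresholds
comparable to a peak's window-dependent range the two effects (larger
windows both widen the range and add competitors) can interact
non-monotonically. The acceptance grid uses thresholds in the
saturated regime.

Detection is noise-sensitive by design (curvature amplifies noise by
1/h²). On fine grids, noise must be brought below the band curvature
scale before detection — by coarser interpolation and/or multi-pass
smoothing; the parameter-recovery tests for the *optimizer* therefore
seed from the noise-free model and fit the noisy data, which isolates
the quantity they measure.

## Decomposition

All profiles are height-parameterized (the amplitude is the value at
the center), so a component can be seeded directly from a detected
peak; areas follow as A·σ·√(2π) (Gaussian) and A·π·γ (Lorentzian). The
Voigt profile is evaluated with the scaled complex error function
(`wofz`) and rescaled to unit height; below σ = 1e−10 or γ = 1e−14 it
switches to its exact limiting form to avoid cancellation.
A pseudo-Voigt approximation was rejected: the exact evaluation costs
little and removes a ~1% shape error.

Initialization: centers and heights from the detected peaks; the width
scale from the measured half-maximum crossing around each peak (the
scan stops where the signal starts rising again, i.e. at an overlapping
neighbor), clipped to [2 grid steps, 10% of the x-span]. A
nearest-neighbor-distance heuristic was tried first and discarded: for
isolated narrow lines it seeds widths orders of magnitude too large and
the joint fit then strands components at their center bounds.

Optimization is `scipy.optimize.least_squares` (trust-region
reflective) over all component parameters jointly, with amplitudes
bounded below by 0, widths by a tiny positive floor, and centers
confined to ±`window_size` grid steps around their seed unless
`free_centers` is set — the bound prevents two components from swapping
places through an intermediate worse fit. The objective is
S = Σ ρ(rᵢ²) with ρ the chosen robust loss (`linear` u, `soft_l1`
2(√(1+u)−1), `huber`, `arctan`), loss scale fixed at 1 in the units of
the (normalized) signal. `max_iter` bounds function evaluations, so a
call can stop early; passing the result back as `warm_start` continues
the same optimization, and the cost sequence over chained calls is
non-increasing. There are no random restarts: identical inputs give
identical decompositions.

## Miller indexing

Bragg's law d = nλ/(2 sin θ) (angles in degrees of 2θ at the interface,
order n = 1 by default) and the tetragonal spacing
1/d² = (h²+k²)/a² + l²/c² are combined by enumerating all triples with
0 ≤ k ≤ h ≤ hkl_max, 0 ≤ l ≤ hkl_max (the h↔k degeneracy is removed up
front; h ≥ k is the canonical representative) and assigning each
observed angle the triple minimizing |2θ_pred − 2θ_obs|, remaining ties
resolving lexicographically. The assignment is purely geometric: no
structure-factor extinction rules are applied, so accidentally
near-degenerate spacings (e.g. (0,0,5) vs (2,0,0) in anatase-like
cells, which real systematic absences would separate) can be labelled
with the geometrically closer but physically forbidden triple.
Extinction filtering and lattice-constant refinement are out of scope.

## Synthetic data

`specdecon.synth` generates spectra with known ground truth: a
component list, a baseline specification (`none`, `affine`, or
`multisine` with periods ≥ 25% of the span, so drift is slow compared
to peaks), and white Gaussian noise from a seeded PCG64 generator —
the same recipe is always bit-identical. Four suites cover the regimes
the pipeline targets, each with recommended analysis settings in
`SUITE_SETTINGS` (detection windows on the order of the FWHM in
samples; stiff arPLS for the drifting suite; no detrending for the
broad overlapped suite):

* `fig1_multisine` — four sharp peaks (σ = 5–6 on a 1000-unit span) on
  an exaggerated multi-sine drift. Sharp peaks are a condition, not a
  convenience: the invariance of per-peak argmax positions between
  airPLS and arPLS detrending holds to one grid step only when peak
  curvature dominates the baseline-slope difference; for broad peaks on
  fine grids it physically does not.
* `fig2_test` — six peaks of mixed heights including a small one
  flanked by two taller neighbors 140 samples away, so the detection
  window can be made to straddle either or both.
* `narrow_xrd` — sharp well-separated lines (FWHM < 1% of span), one
  member with an affine background; one line pair sits 20 units apart
  to exercise close-line resolution.
* `broad_uvvis` — two/three strongly overlapping broad bands (a center
  separation smaller than the summed widths) over a small slow drift.

What the generator does **not** emulate: heteroscedastic or shot noise,
cosmic-ray spikes, detector saturation, wavelength-dependent
instrument response, and baselines correlated with the signal. Passing
tests on these suites show the algorithms implement their contracts and
recover known ground truth under the stated conditions; they do not
certify detection performance on low-SNR experimental data, where
window, threshold, and smoothing choices dominate.

## Problem sizes and tolerances

The test suites use grids of 500–10 000 points and up to six
components, sizes at which every stage runs in well under a second and
the full suite in tens of seconds. Solver-oracle agreement is asserted
at 1e−8 (max-norm, n ≤ 200 against a dense solve), profile limiting
forms at 1e−6, noiseless parameter recovery at 1e−3 grid steps
(centers), 1% (heights), 2% (widths), and noisy-center recovery at half
a grid step with a fixed seed. The λ→0 and λ→∞ baseline limits are
asserted at 1e−6 and 1e−4 respectively.
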