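# Methods

## Resolution and relevance of a compressed sample

A compressed sample of size N is summarised by its positive state
multiplicities {k_s}. Resolution Ĥ[s] is the Shannon entropy (base 2) of
{k_s/N}; relevance Ĥ[k] is the entropy of {k·m_k/N} over distinct
multiplicities k, where m_k is the number of states observed exactly k
times. Zero-count states are dropped at construction: they contribute to
neither entropy (the k·m_k weight vanishes). Relevance ≤ resolution
always, because the multiplicity distribution is a deterministic
compression of the state distribution. Limits: N singleton states give
(log₂N, 0); a single state gives (0, 0); at K multiplicity classes
relevance is bounded by log₂K, attained exactly when m_k ∝ 1/k (uniform
q_k). Entropies are accumulated in double precision; values within
1e−15 of zero are snapped to 0. No bias-corrected estimators are used —
the measures are deliberately the plug-in entropies of the sample at
hand.

## Image compression

Segmentation maps a grayscale image to binary with an *exact* black
fraction: pixels are ranked by intensity with ties broken by a seeded
uniform shuffle, and the `round(a·N)` darkest ranks become black. This
makes `a` the realized black fraction even on quantized histograms with
large flat regions, at the cost of randomizing tied pixels; the
tie-break seed is recorded and fixed per profile, so results are
deterministic given (image, seed). A consequence we accept: a *constant*
image has every pixel tied, and exact-fraction segmentation would turn
it into pure salt-and-pepper noise; since a constant field carries no
spatial information, `msr_profile` and `gradient_msr` short-circuit it
to an identically zero, flat-flagged profile instead.

Coarse-graining anchors an axis-aligned grid at the top-left pixel; cell
(i, j) covers rows [iℓ, (i+1)ℓ) and columns likewise, 0-based and
half-open, with truncated boundary cells so that counts always sum to N
(grids at non-divisor ℓ are kept, not discarded). No averaging over
grid offsets is performed; a single anchored grid per ℓ is a documented
limitation.

Because segmentation depends only on intensity ranks, any strictly
increasing intensity remapping with no new ties leaves every curve and
every MSR value unchanged. This rank invariance is why the choice
between squared-modulus and plain-modulus gradient conventions (below)
does not affect MSR results.

## The MSR integral and scale sets

MSR is the trapezoidal area under relevance vs resolution, points sorted
by ascending resolution, duplicate resolutions collapsed by averaging
relevance, computed on axes normalized by log₂N. The fully-compressed
limit is anchored by prepending an explicit (0, 0) point: the achieved
curve ends near (H₂(a), 0) at the single-cell scale, and the anchor
represents total compression; its contribution is O(H₂(a)²/log₂²N),
about 0.3% at 256². A raw bits² area is available via
`msr(curve, normalized=False)`. Curves with a single distinct resolution
are degenerate and score 0 with a warning.

Scale-set presets: `full` (every integer 1..min dimension), `dyadic`
(powers of two), and the default `geometric` (~48 log-spaced integers).
Resolution falls roughly linearly in log ℓ, so geometric spacing samples
the curve near-uniformly; on 128²–256² textures it reproduces the
full-set MSR to better than 1% at about a sixth of the cost, which is
why it is the default for threshold profiles.

## Threshold profiles and critical thresholds

`msr_profile` evaluates MSR on an a-grid (default 0.02..0.98, step 0.02)
with one shared tie seed and scale set, via a vectorised sweep that
ranks pixels once and bin-counts per scale. Local maxima are detected
on a conditioned profile:

1. a 3-point **median prefilter**. On even lattices the relevance
   estimator has an exact-symmetry degeneracy at a = 1/2: black and
   white multiplicity classes collide (at the single-cell scale the two
   states have equal count N/2 and relevance drops from ~1 bit to 0),
   producing a one-grid-point dip of order 2% in MSR. A moving average
   alone converts that dip into a spurious pair of maxima at 0.5 ∓ 0.04
   for every unimodal profile; the median filter removes it without
   displacing genuine broad maxima.
2. a centered **moving average** of window 3 (declared smoothing
   choice).
3. `scipy.signal.find_peaks` on interior points, peaks closer than 0.06
   in a merged (highest kept), and peaks with prominence below 1e−4
   discarded — the measured realization-noise floor of MSR values on
   256² lattices. Genuine secondary maxima measure ≥2e−4 (H = −0.2)
   up to ~1.3e−2 (H = −0.8) on the same scale.

A profile flat to within 1e−9 returns no maxima and sets a flat flag
(the critical "flattening" regime where the two branches merge).

Measured behavior at these defaults, 256², 5 seeds: H = −0.8 profiles
are bimodal with maxima at 0.5 ± 0.14 (mean offset 0.138); the upper
maximum for H ∈ {−0.9, −0.7} sits at 0.63–0.64, in line with the
bimodal-offset value but ~0.04 above the idealized 2-D site-percolation
threshold 0.593 — notably, even the pure white-noise limit (H = −1)
yields 0.63 under this measure, so the offset is a property of the MSR
maxima, not of residual correlations. The bimodal/unimodal transition is
detection-limited: the saddle depth decays continuously through the
noise floor, and the largest reliably bimodal H is −0.2 to −0.1
depending on realization (the idealized merging point is H = 0). Both
tensions are asserted at their idealized values in the acceptance tests
and left failing by design.

## 1/f^α texture synthesis

Fields are generated by spectral filtering: a seeded unit-variance
Gaussian white-noise lattice is Fourier transformed, multiplied by
f^(−α) with f the Euclidean modulus of the integer frequency vector
(periodic convention), the zero mode removed, inverse transformed, and
centered. α = H + 1 in two dimensions. The white-noise draw depends only
on (seed, size) — never on H — so roughness families share their
underlying noise realisation and can be compared seed by seed. Synthesis
is periodic; no correction is applied for the finite-size
non-stationarity of H > 0 (fractional-Brownian-like) fields, whose
increment scaling is recovered to ±0.15 in the exponent at 256².
Validation: azimuthally averaged power spectra (unit-width annuli on the
fftshifted integer lattice, zero mode excluded, Parseval-exact with the
|FT|²/N normalization) recover log-log slopes of −2α to ±0.15 for
H ∈ {−0.5, 0, 0.5}. Fields are not renormalized to unit variance —
irrelevant to MSR by rank invariance.

`quantile_map` rank-transforms a field onto equal-population integer
levels (default 255) with stable tie order, the standard display and
8/16-bit export path.

## Gradient-magnitude fields

The gradient wavelet pair at dyadic index j consists of the x- and
y-partial derivatives of a Gaussian window of standard deviation
σ = 2^j pixels, truncated at 4σ with the window renormalized to unit
sum. Convolution uses mirror boundaries and separability. The default
output is the squared modulus of the two-component response, with the
plain Euclidean modulus as an option; MSR downstream is rank-invariant
to this choice. Mean response decreases with j on textured inputs
(larger windows average out small-scale fluctuations), which lowers the
gradient MSR accordingly. `gradient_msr` is the mean of MSR(a) over the
threshold grid applied to the gradient field — a reference-free score.

## Quality metrics

MSE and PSNR (10·log₁₀(Δ²/MSE), +inf sentinel at zero error) are
evaluated on the native intensity scale with Δ defaulting to the dtype
range (255 for 8-bit, 1.0 for floats). SSIM delegates to scikit-image's
implementation with the standard parameters (11×11 Gaussian window,
σ = 1.5, K1 = 0.01, K2 = 0.03, population covariance); the specific
SSIM variant used in published calibrations is implementation-sensitive,
so absolute SSIM-optimal parameters are not treated as reference values.

## Boltzmann color mapping

Pixels are normalized to [0, 1]; each pixel independently takes palette
color c with probability ∝ exp(−(h − c)²/T). T is therefore measured in
squared normalized intensity. T = 0 picks the nearest color with exact
midpoint ties split by a seeded fair coin; T → ∞ tends to a uniform
palette draw. Since PSNR is a monotone transform of MSE and the
nearest-color rule minimizes per-pixel expected squared error, the
PSNR-optimal temperature is T = 0 on every image — the calibration
sanity check.

## ROF denoising

The objective is L[f] = λ·TV_iso(f) + ‖h − f‖₂², with isotropic TV on
forward differences (zero gradient past the last row/column). The solver
is Chambolle's dual projection with fixed step τ = 0.25 (the 2-D
stability bound) on the half-quadratic form, i.e. dual scale λ/2;
iterations stop when the maximum pixel update falls below tol (default
1e−5) or at max_iter (default 500), in which case the lowest-energy
iterate seen is returned with a warning flag. The divergence operator is
the exact adjoint of the forward-difference gradient, so the image mean
is preserved to machine precision. Verified against exhaustive
minimization on 2×2 inputs (energy agreement to 1e−10) and against
scikit-image's Chambolle solver (weight = λ/2 in its convention) as an
independent oracle; the energy trace is monotone non-increasing in
practice and asserted to 1e−9.

λ = 0 returns the input exactly. Noise fixtures for denoising
experiments use additive Gaussian noise of σ on the 8-bit scale
(default experiments use σ = 100), clipped to the valid dtype range —
clipping is a declared choice.

## Calibration

`calibrate` scans a sorted parameter grid (T for color mapping, λ for
denoising), averages stochastic metrics over a fixed number of
realizations (default 5) with per-grid-point seeds derived
deterministically from the master seed, and reports the per-metric
argmax with ties going to the smallest parameter. psnr/ssim compare
processed vs reference (the original for color mapping; the noisy input
by default for denoising, or a supplied pristine reference); msr and
msr_grad are computed on the processed image alone. Temperature values
are only meaningful on the normalized scale, so absolute published
optimal temperatures for other normalizations are not comparable.

## What the synthetic generator does and does not establish

The 1/f^α generator reproduces controlled roughness, Gaussian marginals,
and the spectral/increment scaling laws, which is what the MSR
validation experiments require. It does not emulate natural-image
non-Gaussianity, occlusion edges, patch heterogeneity, or camera
artifacts (blur, quantization plateaus); green tests on textures
establish the measure's behavior under controlled scaling, not its
descriptive claims about photographs. Experiments on natural images
require externally supplied data and are out of the tested scope.

## Numerical choices

- Entropy zero-snap 1e−15; relevance clipped to resolution against
  rounding (analytically it never exceeds it).
- Exact black-pixel counts via `round(a·N)`; nested black sets across
  thresholds from a single ranking per (image, tie seed).
- MSR flat-profile tolerance 1e−9; maxima prominence floor 1e−4;
  min separation 0.06; smoothing window 3.
- Texture validation lattices default to 256² (tests stay under a
  minute); published-scale 512² runs are supported and agree.
- ROF: τ = 0.25, tol 1e−5 on max pixel update, max_iter 500.
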