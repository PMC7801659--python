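# Methods

Models, parameter choices and numerical details for each analysis
stage. All defaults are stated with units; tolerances quoted here are
the ones enforced by the test suite.

## Imaging and morphometry

**Segmentation.** Puncta are segmented from a single fluorescence
channel by Otsu thresholding. The threshold is computed on a 3×3
median-filtered copy of the image (robust to shot noise) but applied to
the raw image, because median filtering erodes objects only a few
pixels across. Connected components use 8-connectivity; objects below
`min_area_px = 4` pixels are discarded as noise. Objects touching the
image border are flagged (`border_warning`) since their shape
descriptors are truncated.

**Shape descriptors.** For area *a* (µm²), perimeter *p* (µm) and major
axis *ℓ* (µm):

- circularity = 4π·a/p², clipped to ≤ 1 (pixelation can push the raw
  ratio slightly above 1 for small objects; a one-pixel object has
  p = 0 and is assigned circularity 1 by convention);
- roundness = 4a/(π·ℓ²);
- solidity = a / convex-hull area; aspect ratio = major/minor axis.

Perimeters follow the scikit-image chain-code convention (a d-pixel
square measures 4(d−1) pixels), so pixelated circles score ≈ 0.92
rather than 1; tests assert > 0.85 for discs of radius ≥ 6 px.

**Fluorescence statistics.** Corrected total cell fluorescence is
CTCF = integrated density − area × mean background, with the background
ROI required to be disjoint from the cell and non-empty; negative CTCF
is flagged rather than silently clipped. Corrected total punctum
fluorescence (CTFP) applies the same correction per punctum using the
diffuse cytoplasmic level as background. Percent punctate fluorescence
is 100·ΣCTFP/CTCF and requires CTCF > 0.

**Registration.** Frames are aligned to the first frame by
phase-correlation translation with 1/20-pixel subpixel refinement;
shifts are applied by spline interpolation with the frame median as
fill value. Tests require agreement with a brute-force shift search
within 0.25 px.

## FRAP

**Candidate filter.** A punctum is eligible for photobleaching when the
stimulation ROI (default area 5.5 µm², chosen inside the 5–6 µm² range
typical of point-scanning bleach spots) covers at most 80 % of its
area, and no other punctum centroid lies within an exclusion radius
(default: twice the candidate's equivalent diameter). Partial bleaching
is required so that the unbleached punctum remainder provides the
recovering pool; neighbors are excluded because their signal
contaminates the ROI. The filter is deterministic and reports a reason
for every rejection.

**FRAP ROI.** The analyzed region is the set difference (pre-bleach
punctum mask) \ (post-bleach punctum mask): exactly the pixels that
lost signal. The post-bleach mask is obtained by Otsu thresholding the
first post-bleach frame restricted to the pre-bleach mask (within that
region there are only two intensity populations, bleached and
unbleached, so the threshold is well posed). An empty difference means
nothing was bleached and is an error; a post mask not contained in the
pre mask indicates movement or segmentation failure and raises a
warning.

**Trace extraction.** The raw trace is the integrated density of the
FRAP ROI divided by a constant reference: the integrated density of the
pre-bleach punctum mask averaged over the pre-bleach frames. A constant
denominator keeps the trace an affine image of the recovery model; a
per-frame denominator (available as `denominator="per_frame"`) makes
the ratio a Möbius, not affine, transform of the model whenever
recovery adds net intensity to the punctum, which biases τ by ~15 % at
τ = 60 s. The per-frame option remains useful when acquisition
photobleaching must cancel out.

**Normalization.** Two anchors: x ↦ (x − F₀)/(F̄_pre − F₀), with F̄_pre
the pre-bleach mean and F₀ the first post-bleach value. By construction
the normalized pre-bleach mean is exactly 1 and the first post-bleach
value exactly 0 (machine precision; enforced at 1e-12 and exact zero).
The map is idempotent. A trace with F̄_pre = F₀ has no bleach contrast
and is rejected.

**Recovery fit.** I(t) = A·(1 − exp(−t/τ)) is fit to the post-bleach
points only by bounded least squares (`scipy.optimize.curve_fit`),
A ∈ [0, 1.5] (values above 1 indicate normalization problems but are
reported, not clipped), τ ∈ (0, 10·t_max]. Initial values: A₀ = mean of
the last three points, τ₀ = first crossing of A₀/2; up to 3 seeded
restarts. τ is the exponential time constant; the half-time of
recovery, t½ = τ·ln 2, is exposed as `t_half_ln2`. When the fitted
amplitude is below 0.02 the time constant is unidentifiable and the fit
is flagged. Accuracy (enforced): noiseless traces recover (A, τ) within
1e-3; with additive ratio noise of sd 0.01, the median absolute error
in A is ≤ 0.05 and the median relative error in τ is ≤ 10 % over the
grid A ∈ {0.3, 0.6, 0.9} × τ ∈ {20, 60, 120} s.

**Acquisition schedule.** Default: 5 pre-bleach frames at 2 s spacing,
then 12 post-bleach frames at 5 s and 36 at 10 s (t = 0 at the first
post-bleach frame; ~7 min total), dense early where recovery is
fastest.

## Punctum-area mixture model

Punctum areas are modeled as a K-component univariate Gaussian mixture
(default K = 2: small P1 and large P2 populations, components sorted by
ascending mean). EM details:

- E-step in log space with log-sum-exp for numerical stability;
- initialization by quantile splits with seeded jitter; default 10
  restarts, best final log-likelihood wins;
- variance floor 1e-6·(data range)² to prevent collapse onto single
  points;
- convergence when the relative log-likelihood change is < 1e-8
  (max 1000 iterations); the recorded log-likelihood history is
  non-decreasing on every run (asserted);
- K = 1 falls back to the closed-form ML solution (1/n variance).

The fit requires at least 2K distinct values. `classify_points` returns
Bayes responsibilities and hard labels; `compare_components` reports
AIC/BIC with 3K − 1 free parameters per model. Accuracy (enforced): at
n = 2000 with weights 0.40/0.60 the component means of all three
reference parameter sets — (0.8, 11.2), (0.4, 8.4) and (0.9, 14.8) µm²
with SDs (0.6, 10.1), (0.3, 8.1), (0.8, 10.7) — are recovered within 3
standard errors, and the EM optimum is never below a dense grid-search
oracle on small samples.

## Biochemistry

**Percent insoluble.** Each band density is corrected as
band/loading-normalizer × volume-factor; percent insoluble =
100·P/(S+P) on corrected values. Supernatant and pellet rows must share
a sample id and a positive corrected total. The quantity is invariant
under common rescaling of both densities (enforced by property tests).

**ThT t50.** Model-free: baseline = mean of the first 5 % of points,
plateau = mean of the last 10 %; t50 is the linearly interpolated first
crossing of the midpoint. The plateau is trusted only if the last 10 %
of the trace is steady (|slope| < 1 % of the span per hour); otherwise
t50 is withheld (`steady_state_reached = False`) rather than
extrapolated. A 4-parameter logistic fit (`tht_t50_logistic`) serves as
a cross-check; both agree within one sampling interval (0.5 h at the
default 0–48 h, 0.5 h grid) on simulated curves. The estimate is
invariant under affine transforms of fluorescence and equivariant under
time rescaling.

**Replicate averaging.** Replicates must share a time grid; mean and
SEM (ddof = 1) are returned per timepoint, with a warning and NaN SEM
for a single replicate.

## Statistics

Implemented from the defining formulas, with scipy used only as a
cross-check in tests:

- **Kruskal–Wallis**: midranks, tie correction
  1 − Σ(t³−t)/(N³−N); all-tied data yield H = 0, p = 1 by convention;
  p from the χ² approximation with k − 1 df. Validated against the
  worked example H = 7.2, against scipy with ties (1e-10), against the
  exact permutation null at n = 8 (within 0.05), and by a type-I error
  in [0.04, 0.06] over 5000 null replicates.
- **Dunn's post-hoc**: z = (R̄ᵢ − R̄ⱼ)/√(V·(1/nᵢ + 1/nⱼ)) with
  V = N(N+1)/12 − Σ(t³−t)/(12(N−1)); Bonferroni adjustment multiplies
  by the number of pairs, capped at 1.
- **One-way ANOVA**: SSB/SSW decomposition, F with (k−1, N−k) df;
  optional Bonferroni pairwise t tests on the pooled within-group
  variance. Zero within-group variance is rejected.

## Synthetic generators

Every generator is seeded (`numpy.random.default_rng`) and returns its
ground truth so tests can close the loop. What they emulate — and do
not:

- **FRAP stacks**: a disc punctum (level 3000) on flat background
  (level 100), bleach to a fraction `bleach_depth = 0.1` of the
  pre-bleach level in the stimulation ROI, exponential recovery,
  optional per-frame drift, Gaussian read noise, and optional global
  acquisition photobleaching. By default recovery adds intensity to the
  ROI without depleting the rest of the punctum; a
  `conserve_punctum=True` mode redistributes the recovered signal from
  the unbleached remainder so the punctum total stays constant. Not
  modeled: diffusion within the ROI (recovery is spatially uniform),
  photophysics beyond a single exponential, detector offsets.
- **FRAP traces**: the ratio trace directly (pre-bleach 1, post-bleach
  bleach_depth + (1 − bleach_depth)·A·(1 − e^(−t/τ)) + noise), for fast
  property-based testing without imaging.
- **Fixed-cell images**: an elliptical cell with a signal budget split
  between diffuse cytoplasm and puncta so the true percent-punctate is
  exactly 100·(1 − diffuse fraction).
- **Area mixtures**: component labels then normal draws; optional
  rejection resampling to truncate at zero (areas are positive; with
  the reference parameter sets truncation shifts small-component means
  by less than the 3-SE recovery tolerance at n = 2000).
- **ThT curves**: 4-parameter logistic plus Gaussian noise.
- **Densitometry**: band densities constructed as
  abundance × normalizer / volume-factor so the corrections invert
  exactly.

## Limitations

- The FRAP model is a single exponential; binding-dominated or
  diffusion-limited recoveries with two timescales will be summarized
  by an effective τ.
- Segmentation assumes a bimodal intensity histogram; dim puncta on
  textured backgrounds may require a different thresholding strategy.
- The mixture model assumes normal components; punctum-area
  distributions with heavy right tails may prefer a log-normal, which
  can be emulated by fitting log-areas.
- The χ² approximation to the Kruskal–Wallis null is used at all group
  sizes; at very small n its p-values deviate from the exact
  permutation null (bounded at 0.05 in tests at n = 8).
- Percent-insoluble assumes quantitative, unsaturated band densities;
  saturated blots violate the linearity the corrections rely on.
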