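# Methods

This note documents the models, estimator dialects and numerical choices
behind `texrep`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design being emulated

The package targets the paired test–retest design used to qualify imaging
biomarkers: each subject undergoes two T2-weighted axial MR acquisitions on
consecutive days on the same unit, a reader segments the tumor on each axial
slice of each study, and the same feature panel is extracted from both
studies. Because no treatment intervenes, per-feature differences between
the two days estimate pure measurement error (acquisition noise plus
re-delineation). The emulated acquisition geometry is a pelvic T2 axial
series: 96×96 in-plane voxels at 0.68 mm, 10 sections at 7.8 mm pitch
(6 mm section thickness + 1.8 mm intersection gap).

## Synthetic phantom model

**Base texture.** A tumor phantom is a stationary correlated Gaussian random
field: white noise convolved with a Gaussian kernel of width
`correlation_length` (mm, converted to voxels per axis), then affinely
standardized to the requested `intensity_mean`/`intensity_sd`. This is the
simplest stationary field with tunable coarseness, chosen so that
co-occurrence, run-length and zone statistics respond monotonically to
`correlation_length` (verified by test). The mask is an ellipsoid with mm
semi-axes `tumor_axes`, its boundary radially perturbed by a smooth random
field scaled by `boundary_irregularity`; the largest connected component is
kept so the tumor is a single body.

**Defaults** (one phantom ≈ 12k in-mask voxels): `correlation_length` 5 mm
(a typical intratumoral texture scale, several in-plane voxels but less than
one slice pitch), `intensity_mean` 300 and `intensity_sd` 60 arbitrary MR
units (20% spatial CV, typical for heterogeneous tumor on T2), `tumor_axes`
(20, 20, 20) mm — a 40 mm tumor, inside the 30–85 mm range reported for the
kind of cohort emulated. Cohort simulation adds between-subject spread:
tumor size and correlation length ±20%, mean signal ±10%, uniform.

**Test–retest model.** Both days share the base field; day *d* observes

    x_d(v) = base(v) · (1 + γ_d + η_d(b(v)))

with γ_d ~ N(0, `noise_cv`) a per-study multiplicative gain and
η_d ~ N(0, `noise_cv`) drawn independently per in-plane block of side
≈ `correlation_length`. The two components have distinct jobs:

- the **study-level gain** γ makes `noise_cv` the true within-subject CV of
  intensity-scale summary features (the volume mean changes by a factor
  1 + γ between days), giving the parameter-recovery tests a known truth;
- the **block-level term** η perturbs spatial texture at the texture's own
  scale. Per-voxel noise would be almost entirely absorbed by 32-bin
  quantization and by the neighborhood averaging inside the texture
  matrices; block noise at the correlation scale survives both.

A design with noise on day 2 only, or with block noise only, fails
parameter recovery: one-sided noise biases the recovered wCV to
`noise_cv`/√2, and independent block noise averages down by 1/√(number of
blocks) in any volume-mean feature. The symmetric two-component model is
therefore used and is the package's declared test–retest model.

**Re-delineation.** `mask_jitter` applies an independent per-slice random
morphological dilation or erosion of radius ≤ `mask_jitter` voxels to the
day-2 mask, mimicking a reader re-drawing each axial contour; erosion never
deletes a slice outright. At the default geometry a 1-voxel jitter changes
a few percent of mask voxels (tested to stay below 20%).

**What the phantoms do not model:** MR physics (coil bias fields, Rician
magnitude noise), partial-volume effects at the tumor boundary, scanner
drift between days, and genuine biological change. Passing tests therefore
demonstrate that the *pipeline and statistics* behave correctly under a
known noise model — not that any particular feature is repeatable on
patient data.

## Preprocessing

Order: smooth → crop → quantize.

- **Smoothing** is strictly 2D per slice (default Gaussian, σ = 2 mm;
  Laplacian-of-Gaussian and none available). The through-plane pitch
  (7.8 mm) is more than ten times the in-plane voxel, so 3D filtering would
  mix anatomically distant tissue. The "medium" scale of 2 mm follows the
  common radiological texture-scale convention; the kernel family and scale
  are config keys (`filter.mode`, `filter.scale_mm`) and every run echoes
  its resolved config, because the smoothing step is the least standardized
  part of such pipelines.
- **Cropping** takes the mask bounding box plus one voxel of padding; the
  in-mask voxel count is conserved exactly (tested).
- **Quantization** uses equal-width bins over the in-mask [min, max]
  intensity range (ROI-relative, the dominant radiomics convention), top
  bin right-closed, default `G = 32`. This makes all bin-level features
  invariant to positive affine intensity rescaling (property-tested).
  A constant ROI maps to bin 1 with a `constant_input` flag rather than an
  error. No resampling and no inter-study intensity normalization are
  performed; the anisotropic geometry is carried as metadata and all
  texture operations work on the voxel lattice in index space.

**First-order moments and the intensity scale.** The quantized volume keeps
its `bin_edges`, and histogram mean/median/SD are computed on bin-center
intensities in original units, while shape moments (skewness, excess
kurtosis; Fisher convention, n denominators), entropy (bits) and energy use
the bin probabilities and are scale-free. Computing location moments on raw
intensity (via bin centers) rather than on bin indices is deliberate:
min–max binning is affine-invariant, so bin-index moments are blind to any
global intensity change between days and would report zero measurement error
for exactly the feature class whose repeatability is of most interest.

## Feature panel (46 features)

The registry (`texrep.registry`) is the single source of truth for names,
classes and output order: 7 histogram + 4 fractal + 12 GLCM + 3 GLDM +
4 NGTDM + 7 GLRL + 9 GLZSM = 46. Features named in the underlying study are
all present; the remaining slots are filled from the classical panels of
each family (Haralick sum average and dissimilarity; Galloway/Chu low/high
gray-level run emphasis; Thibault low/high gray-level zone emphasis and
zone-size variance). This composition is a documented reconstruction — the
exact published composition lives in supplementary tables that are not
available in text form.

Naming of the "variability" features follows the classical definitions:
GLRL *intensity variability* ≡ gray-level nonuniformity (GLN); GLZSM
*intensity nonuniformity* ≡ GLN over zones; GLZSM *intensity variability* ≡
gray-level variance across zones; GLZSM *size zone variability* ≡ zone-size
nonuniformity. This mapping is this package's declared dialect.

**Second order (GLCM/GLDM).** Distance 1, four in-plane directions
(0,1), (1,0), (1,1), (1,−1), honoring the in-plane definition of
second-order features under thick slices. Counts are pooled across
directions and slices into one matrix before normalization — better
conditioned than per-direction feature averaging on small masked regions —
and the GLCM is symmetrized. Only pairs with both voxels in-mask count.
Gray-level indices in moment-type features are bin numbers 1..G; entropies
are in bits with 0·log 0 ≡ 0. The GLDM is built from the same pair set and
must equal the |i−j| marginal of the GLCM (cross-checked numerically), which
also forces GLDM contrast ≡ GLCM contrast.

**High order (NGTDM/GLRLM/GLZSM).** These families describe multiplanar
structure, so the defaults are 3D: 26-voxel NGTDM neighborhood (center and
out-of-mask voxels excluded from the neighborhood mean), 26-connectivity
zones, and the 13 unique 3D run directions. In-plane-only variants
(8-neighborhood / 8 in-plane directions / 6-connectivity) are available via
`texture.high_order_geometry: 2d` for users who consider 7.8 mm too coarse
for through-plane adjacency. Formulations are the classical ones
(Amadasun–King; Galloway; Thibault): matrices hold raw counts, features
normalize at the end. Mass conservation (Σ z·s = N_p for zones;
Σ r·l = N_p·D for runs) is asserted on every computation. NGTDM coarseness
uses ε = 10⁻¹² in its denominator and is capped at 1/ε (the cap value is the
reported degenerate value for constant input).

**Fractal estimators.** Box-counting FD uses the differential (gray-level
surface) variant per slice: dyadic box sizes {2, 4, 8, 16} clipped to the
slice bounding box, box height scaled as s·G/M, least-squares slope of
log N(s) against log(1/s); a slice supporting fewer than four scales is
skipped with a flag. Per-slice estimates are aggregated as mean and SD
across slices — the reported FD mean *and* SD imply per-slice estimation,
and 2D slices sidestep the anisotropic slice gap. A filled constant region
recovers FD = 2 and a one-pixel line FD = 1 (analytic limits, tested).
Lacunarity is the gliding-box statistic Λ(r) = 1 + var(M)/mean(M)² of the
in-mask box mass (sum of gray levels — intensity lacunarity, not binary),
with boxes touching out-of-mask voxels excluded, averaged over box sizes
{2, 4, 8}; a constant image gives exactly 1. The Hurst exponent uses
rescaled-range analysis over in-mask row/column profiles (minimum length 8,
dyadic windows): the slope of log[(R/S)/E₀(R/S)] against log window length
plus 0.5, where E₀ is the Anis–Lloyd/Peters finite-sample expectation of
R/S for i.i.d. data. The correction removes the well-known upward bias of
naive R/S at short windows, making white noise recover H = 0.5 in
expectation (tested to ±0.1); smoothed fields test persistently above it and
a linear ramp near 1. R/S is the simplest defensible estimator for the
short, masked profiles a tumor ROI yields; spectral estimators need longer
uninterrupted series.

## Repeatability statistics

Implemented exactly as stated in the README formulas; choices worth
recording:

- the wCV denominator is the mean of all 2n pooled measurements (the
  alternative — mean of per-subject means — differs only with missing data,
  which the pairing validator disallows);
- limits-of-agreement CIs use t₀.₉₇₅,ₙ₋₁·√(3s²/n), the standard
  large-sample variance of an estimated limit;
- band boundaries: exactly 10% is "good", exactly 50% is "unreliable";
- a zero or sign-mixed measurement scale makes a CV meaningless; such
  features are flagged `not-interpretable` and excluded from
  classification rather than silently classified;
- with two readers, statistics are computed independently per `reader_id`
  (separate per-observer tables); no pooled or inter-reader statistic is
  produced.

The identity r = 1.96·√2·s_w and the 95% coverage interpretation of r are
both verified in tests (the latter by Monte-Carlo at n = 10⁵).

## Pipeline behavior

Feature extraction is error-isolated per family: an exception inside one
family records NaN plus a flag for that family's features and the run
continues. Every run is deterministic given its seeds (tested end-to-end,
including the CLI). Outputs are CSV (long-format features; one
repeatability table per feature class per reader, numbered 2–8 in registry
order) plus a resolved-config echo.

## Simulation sizes

Problem sizes used by the test suite and acceptance script are chosen to
make Monte-Carlo tolerances meaningful at interactive runtimes: oracle
equivalence uses ≥100 random 6×6×3 volumes at G ∈ {2,3,4} (small enough for
pure-Python brute force, large enough to exercise all mask/boundary paths);
wCV parameter recovery uses n = 200 subjects at default phantom geometry
(SE of the wCV estimate ≈ 0.5 percentage points, so the [8, 12]% window is
≈ ±4 SE); the re-delineation study uses 20 seeds × 8 subjects on a reduced
48×48×8 grid. The repeatability-coefficient coverage check uses 10⁵
simulated differences.

## Known limitations

- The exact smoothing filter and the binning reference (ROI-relative vs
  slice-relative) of the emulated workflow are not recoverable; both are
  exposed as config with documented defaults.
- Fractal and Hurst estimator dialects are declared choices among several
  in common use; absolute values are dialect-dependent even though
  repeatability statistics of them are meaningful.
- The phantom noise model is multiplicative and Gaussian; heavy-tailed or
  structured artifacts (motion, susceptibility) are out of scope.
- Single-voxel-wide or very small ROIs degrade gracefully (flags, skipped
  slices) but their feature values are of little scientific use.
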