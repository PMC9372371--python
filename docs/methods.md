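# Methods

This note documents the models and procedures implemented in `histodti`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic phantoms do and do not establish about real data.

## DTI scalar metrics (`histodti.dti`)

Inputs are sorted diffusion-tensor eigenvalues λ₁ ≥ λ₂ ≥ λ₃ (mm²/s);
tensor estimation from raw diffusion-weighted data is upstream and out of
scope. The Westin shape indices use the trace-normalised convention
(factors 1, 2, 3): this is the convention under which CL = 1 − CP − CS
holds exactly together with AD = 3·MD − 2·RD, the two identities the
regression layer relies on to detect redundant predictors. The classical
λ₁-normalised variant is available via `westin_norm="lambda1"` but is not
the default. Negative eigenvalues (possible in noisy fits) are rejected by
default; `clamp_negative=True` clamps them to zero for real-data use —
silent clamping is not the default because it would hide fit pathologies.
An all-zero triple is an error (shape indices are undefined at zero trace),
not a NaN.

## Cell counting (`histodti.cell_density`)

Classical pipeline for dark somata on a bright background: invert,
flatten (subtract a Gaussian background, σ = 20 µm), global threshold
(Otsu on the ROI's flattened intensities by default, or an explicit
level), single-pixel opening, connected components, area filter
(default 7–700 µm² — sub-nucleus debris to large soma), and an optional
distance-transform watershed that splits touching somata. Segmentation
runs on the full frame; a cell belongs to the ROI that contains its
centroid, which makes counts additive over disjoint ROIs. A featureless
ROI (intensity range below `min_contrast`, default 8 levels) short-circuits
to zero cells, because Otsu on pure noise would hallucinate foreground.
CD is reported per mm², keeping values O(10²–10⁴) for realistic densities.

## Structure-tensor anisotropy (`histodti.structure_tensor`)

Gradients come from truncated Gaussian-derivative kernels (size 11 px,
σ = 3 px); the per-pixel gradient outer product is integrated with a
Gaussian window (σ = 3 px, matching the derivative scale, since the
integration window is otherwise a free choice). All convolutions use
reflect padding to avoid spurious edge gradients. The per-pixel anisotropy
index AI = (μ₁−μ₂)/(μ₁+μ₂) is the standard normalised 2D eigenvalue
difference, bounded in [0, 1]; the ROI value is the mean of per-pixel AI
over pixels whose tensor trace exceeds 10⁻⁶ of the field maximum (flat
pixels carry no orientation and would contribute 0/0). The alternative
aggregation — AI of the ROI-summed tensor — is exposed via
`aggregation="roi_tensor"` for sensitivity checks. AI is invariant to
global linear intensity rescaling and covariant under rotation.

## Skeleton morphometry (`histodti.skeleton`)

The grayscale-to-binary cascade follows the order bandpass → rolling-ball →
rescale → unsharp → despeckle → threshold → binary clean-up. The bandpass
is realised as a difference of Gaussians with σ = structure_size/2 per
bound and the image mean restored, matching the passband semantics of the
FFT bandpass used in image-analysis GUIs without reproducing their dialect.
The rolling ball (radius 200 px) runs on the inverted image (stain dark,
background light) and is evaluated on a downsampled copy for large radii —
the background is smooth at that scale by construction. "Despeckle" is the
conventional 3×3 median; "remove outliers" replaces a pixel by the local
median when it deviates by more than 50 levels within a 2 px radius (the
original values are unstated; these are the common defaults). Thresholding
treats the published ranges (e.g. 0–218 for the corpus callosum) as
inclusive intensity windows on the processed image with stained structures
dark.

Thinning uses the topology-preserving 2D algorithm from scikit-image.
Skeleton voxels are classified by 8-neighbour count (endpoint < 2,
slab = 2, junction > 2; the three classes partition the skeleton), adjacent
junction voxels are merged, and branches are traced as slab paths with
Euclidean step lengths (1 or √2 px) × pixel size. Two analyzer details
matter for exact topology:

- **Junction fusion (default 10 px).** Thinning splits a 4-way crossing
  into two triple-point clusters joined by a short slab path (occasionally
  a short loop) whose length scales with the process width. Junction
  clusters joined by a connector at most `junction_fusion_px` long are
  contracted into one junction and the connector is not counted as a
  branch. 10 px is about one process width at the default geometry and an
  order of magnitude below genuine branch lengths; set 0 to keep raw
  clusters (the behaviour of the plugin family this emulates).
- **Fragment filter.** Connected pieces with exactly two endpoint voxels,
  no junctions, and total length < 0.7 µm are deleted before totals, per
  the published debris rule; isolated single-voxel components (zero length,
  one endpoint voxel — the thinned remnant of sub-resolution debris) fall
  under the same rule. The filter is applied per component before
  summation, is idempotent, and only ever decreases the count metrics.
  Lengths are compared in µm after geometric measurement, not in pixel
  steps.

`average_length` = total branch length / branch count; with zero branches
it is reported as NaN.

## Estimation statistics (`histodti.stats`)

Cohen's d standardises the SE-minus-control mean difference by the pooled
SD (n−1 variances); both induction models are pooled into one SE group by
label. BCa intervals compute the bias correction z₀ from the fraction of
bootstrap replicates below the estimate (ties counted half) and the
acceleration from jackknife skewness over all observations; groups are
resampled independently (default 5,000 replicates — the source count is
unstated; permutations default to the published 100,000). "Studentised"
is read as the Welch t statistic. When C(n₁+n₂, n₁) is small enough the
permutation test enumerates all splits and returns the exact proportion;
otherwise it samples labels and applies the add-one convention
p = (hits + 1)/(n_perm + 1) for validity, with the raw proportion also
available (`return_details=True`). Constant pooled data returns p = 1 by
convention. BH-FDR is the step-up adjustment, applied within each
reporting family (one family per output table); CIs are left uncorrected.

## Predictive model (`histodti.model`)

Ordinary least squares of each histological parameter on
x = (FA, RD, MD, CP, CS), pooling all animals and regions. Predictors stay
on their native scales (the reported fits are raw-scale); rows with missing
values are dropped listwise per response with n reported. Requesting AD or
CL alongside their complements raises `SingularDesignError` naming the
exact identity. The 95% CI for R² is an accelerated bootstrap that
resamples whole animals as blocks, because rows within an animal are not
independent — a known violation of the pooled model's error assumption.
Adjusted R² and F follow their closed forms and are cross-checked against
statsmodels in the tests.

Leave-one-animal-out CV holds out all of an animal's regions together;
leave-one-region-out CV reports both per-held-out-region R and the pooled R
over concatenated held-out predictions (the published table does not define
its columns; both readings are computed). Q² uses the grand mean of the
true values in the denominator.

### Structural collinearity and what it implies

All seven scalar metrics are functions of three eigenvalues; FA is an
*exact* nonlinear function of (CP, CS). The five-predictor design is
therefore full rank only through the curvature of those maps, and the
variance of individual coefficient estimates is enormous even when the
model's explanatory and predictive accuracy is excellent. Measured on the
default cohorts at population R² = 0.8 (n = 68), per-cohort coefficient
SDs are 1.3–12× the true coefficient magnitudes, so even the mean over 200
cohorts carries a 10–90% standard error per coordinate. Coefficient-level
recovery at a 5% tolerance is consequently not achievable under these
conditions — only predictions, R², and cross-validated metrics are stable
— and the corresponding assertion in the acceptance-style test suite fails
by design as an honest record of this limit. Interpret fitted coefficients
as a predictive bundle, never individually.

## Synthetic phantoms (`histodti.phantoms`)

One integer seed feeds a per-generator spawned random stream, so outputs
are bit-reproducible and generators never perturb one another.

- **Nissl phantoms**: dark disks (radius 2.5–5 µm, intensity 60) on a
  bright background (200) at 0.114 µm/px, non-overlapping by default
  (minimum centre distance 2·r_max + 1 µm, rejection sampling with bounded
  retries); `allow_touching` exercises the watershed path. Gaussian noise
  is added before 8-bit quantisation.
- **Fiber phantoms**: line segments with axial von-Mises orientations
  (κ = 0 → uniform; the doubled angle carries the concentration),
  anti-aliased by a 1 px linear coverage rolloff, default width 1 µm.
  The drawn orientations and their axial circular variance are recorded.
- **Astrocyte phantoms**: trees with 3–4 primary processes radiating from
  a root, binary tip splits down to depth 2, segments 5–9 µm, stamped as
  8-connected Bresenham centerlines and dilated to a 1 µm width. Segment
  placement is collision-checked (unrelated segments stay ≥ 2·radius + 4 px
  apart, with an exemption near shared nodes) and trees keep disjoint reach
  discs, so the recorded topology (branches, junctions, endpoints,
  triple/quadruple points, centerline length) is unambiguous ground truth.
  Optional sub-cut-off debris segments (0.3–0.45 µm) are planted isolated
  for fragment-filter checks.
- **Cohort tables**: 17 animals (4 controls + 13 SE, the pooled design) ×
  4 regions. Per (group, region) eigenvalue distributions emulate rat
  brain at high field — an anisotropic corpus callosum, near-isotropic
  cortex, and post-SE shifts (higher FA and MD, lower CS) in CA3b and
  layer VI — with SDs of roughly 5–10%, representing animal-to-animal and
  ROI variation. The distributions deliberately vary *all five* derived
  predictors across cells; with nearly constant MD the regression design
  would be ill-conditioned beyond what the structural collinearity already
  imposes. Each histological response is bᵀx + c + N(0, σ); the default σ
  (0.12905) is the output of `calibrate_noise_sd`, a fixed-seed Monte-Carlo
  calibration to population R² = 0.8. Draws violating λ₁ ≥ λ₂ ≥ λ₃ > 0 are
  redrawn.

What the phantoms do **not** emulate: staining variability, uneven
illumination beyond smooth backgrounds, overlapping astrocyte territories,
3D structure projected into 2D, partial-volume effects in DTI, or any
nonlinearity in the DTI–histology relation. Passing tests therefore
establish the correctness of the computations, not the biological accuracy
of the published effect sizes, which are bound to the original animals'
data.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations for a
single CPU: 25–50 astrocyte phantoms of 1024² px, 512² cell phantoms at
0.228 µm/px (25 cells), 256² fiber phantoms, 500 BCa coverage draws at
n = 20 + 20 with 1,000 bootstrap replicates, and 200 cohorts per model
property. Grating checks use period 8 px, well resolved by the σ = 3 px
derivative kernels, with the default integration window spanning two-plus
periods. Tolerances: tensor identities at 10⁻¹² relative error; phantom
branch length within 5% of the centerline truth (thinning shortens tips by
about half a process width and discretises steps to 1/√2 px); adjusted-R²
worked examples at 10⁻³ absolute (the published R² inputs are rounded to
three decimals).
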