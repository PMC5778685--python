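# Methods

This note documents the models, numerical choices and known limitations of
`hippoatlas`. It is written for someone who wants to understand *why* the
pipeline behaves as it does, not just how to call it.

## Segmentation model

The pipeline is a multi-atlas scheme with machine-learning label fusion.
Labelled training scans ("atlases") are warped onto a common template; a
peri-hippocampal volume of interest (VOI) is traced on the template; voxel
classifiers trained per atlas are combined, and the fused score map is
binarized with a Bayesian threshold.

**Spatial normalization.** Intensities are min–max normalized to [0,1]
(a constant image maps to zeros rather than NaN so degenerate inputs cannot
poison a batch). Registration is intentionally simple and fully
self-contained: a three-level multi-resolution Powell search minimizing the
mean squared intensity difference over a 12-parameter affine
(translation, Euler rotations, log-scales, shears; the matrix is built as
R·diag(exp s)·Shear so it is invertible by construction), followed by an
optional demons-like refinement (intensity-difference forces, Gaussian
smoothing of each update with σ = 1.5 voxels plus a light σ = 0.5 diffusion
of the accumulated field). Transforms use the pull convention — they map
fixed-space voxel coordinates to moving-space coordinates — and masks are
resampled with nearest-neighbour / 0.5-threshold rules. On the synthetic
phantoms (rigid pose jitter up to ±3 voxels, ±5°) the affine stage recovers
translations to < 0.1 voxel and rotations to < 1°; the demons stage exists to
absorb residual shape differences (for example hippocampi of different
volume) and keeps the field Jacobian positive at the default regularization.
Non-convergence is reported as a flagged result (`converged=False` when the
final cost is not at least halved), never an exception.

**Bias-field correction.** Rather than reimplementing a full N3/N4-style
histogram-sharpening estimator, the correction models the field as
exp(low-order 3-D polynomial) fitted in the log domain. A plain polynomial fit of log-intensities would absorb anatomy (on a
piecewise-constant phantom it would "correct" the tissue layout itself), so
the fit is applied to *class-residual* log-intensities: foreground voxels are
clustered by intensity (deterministic 1-D k-means, k = 4, run from both a
farthest-point and a quantile seeding, keeping the lower-SSE solution), the
class mean is subtracted per voxel, and the polynomial (default order 2) is
fitted to the residuals over two outer iterations. The exponentiated,
mean-normalized field is divided out and the image renormalized. Operating
range: multiplicative ramps up to roughly ±12% of the mean intensity are
removed almost completely (>99% RMS reduction on phantoms); much stronger
fields make tissue intensity ranges overlap and the estimate degrades.
`order=0` degenerates to a global rescale by design.

**Template.** The population template is the iterated mean: rigid-align all
scans to the first, average, then (default 2 iterations) affine-register all
scans to the current mean and re-average. Two iterations are enough for the
phantom populations the package targets.

**VOI.** The shape-analysis VOI of the original pipeline is replaced by a
label-probability construction: the voxelwise mean of the warped training
masks is thresholded at zero support and its bounding box, padded by 2
voxels and clipped to the grid, becomes the VOI. This guarantees the
contract that every warped training hippocampus is contained in the VOI.
Left and right hippocampi get separate VOIs and are processed independently
end to end, since volumes are reported per side.

**Features.** Every VOI voxel is described by 37 features: 4 central-moment
statistics (mean, population sd, skewness, excess kurtosis — zero-variance
neighbourhoods return 0 for the standardized moments) on cubic boxes of edge
3/5/7/9 with mirror padding; 5 Haralick features (energy, contrast,
correlation, homogeneity, entropy) from a symmetric gray-level co-occurrence
matrix, quantized to 8 equal-width bins over the whole-VOI range (per-patch
quantization would make GLCMs incomparable across voxels), accumulated per
offset over the 13 unique 3-D unit offsets with both pair endpoints inside
the (boundary-clipped) 5³ patch, features averaged over offsets — a constant
patch yields energy 1, contrast 0, entropy 0, and correlation is defined as
0 when the marginal variance vanishes; and 4 Haar-like responses (half-box
mean differences along each axis, centre plane excluded, plus
centre-minus-surround) per box edge 3/5/7/9, evaluated through an integral
volume with boundary boxes clipped and normalized by the voxels actually
covered. Feature columns are z-scored with statistics accumulated from the
training VOIs only; zero-variance columns are dropped with a warning and
recorded in the schema.

**Voxel classifiers and fusion.** One feed-forward network per atlas: a
single hidden layer of ten sigmoid units and a sigmoid output, trained by
minibatch stochastic gradient descent with momentum on the log-loss
(defaults: learning rate 0.01, momentum 0.9, 50 epochs, batch 32), written
directly in numpy so training is bit-reproducible from the seed. Background
voxels dominate the VOI (prior ≈ 0.15–0.25), so training uses a seeded 1:1
class-balanced subsample capped at 6000 voxels. For a test scan the m = 10
best-correlated atlases (ties keep input order; atlases with r ≤ 0 are
excluded to preserve convexity) score every VOI voxel; scores are averaged
with the correlations normalized to sum to one, so the fused map is a convex
combination. The binarization threshold is the posterior probability
t = S·P(H) / (S·P(H) + (1 − s)(1 − P(H))) with S, s the repeated stratified
5-fold cross-validated sensitivity/specificity (averaged over the selected
atlases) and P(H) the mean fraction of hippocampal voxels in the VOI across
training scans. Voxels are kept on strict inequality (score > t). With the
well-separated classifiers the phantoms produce (S, s ≈ 0.97–0.99) the
threshold lands around 0.8–0.9, which under-segments slightly; Dice against
ground truth on the default 64³ configuration is ≈ 0.9.

Pipeline defaults use 2 CV repeats rather than a larger count: each fold
holds thousands of voxels, so the Monte-Carlo error of (S, s) is already far
below the sensitivity of t to them, and further repeats only cost time. The
repeat count is config-exposed (`cv_repeats`), and the standalone
`cv_sensitivity_specificity` defaults to 10 repeats.

**Measurement space.** Volumes are measured in template space (voxel count ×
voxel volume of the thresholded fused map). An inverse affine is available
(`AffineTransform.inverse`) for native-space work, and
`SegmentationResult.mask_to_template` carries native ground-truth masks into
template space for evaluation.

## Diagnostics model

The clinical layer treats the segmented volume as a scalar biomarker.

- **Precision** is the sd of screening − repeat residuals (two acquisitions
  weeks apart, assumed morphologically identical), reported in mm³ and as a
  percentage of a reference mean volume, with a one-sample t-test for a null
  mean. Sample (n−1) standard deviations are used throughout the
  diagnostics layer.
- **Aging model**: OLS of control volumes on (age − t₀), t₀ = minimum cohort
  age (pass the whole-cohort minimum explicitly when fitting on a CTRL
  subset). Reported with the slope's 95% CI, both standard errors and R².
- **Detrending**: V_eff = V̂(age) − V, implemented exactly in this
  orientation, so V_eff is an atrophy *deficit* (larger = more missing
  volume) and is used directly as the disease-positive ROC score; raw-volume
  ROC uses −V instead.
- **ROC/AUC**: threshold sweep over the scores, trapezoidal AUC (equal to the
  Mann–Whitney concordance with ties half-weighted — asserted against a
  brute-force oracle), Hanley–McNeil closed-form SE and a class-stratified
  bootstrap SE (default 500 resamples, seeded).
- **Group tests**: tie-corrected Kruskal–Wallis with the chi-square
  approximation (exact small-sample p-values are out of scope), and a
  Gaussian Naive Bayes three-class cross-validation (10-fold, 100 rounds;
  accuracy over all classes, sensitivity/specificity with AD as positive and
  CTRL+MCI as negative). Gaussian class conditionals are the natural choice
  for a volume feature.

## Synthetic data

The generator defines the study conditions for every test.

**Phantoms** (`PhantomSpec`): 64³ grid at 1 mm isotropic (desk-scale rather
than MRI-native 256³, so the full pipeline runs in minutes on one CPU). A
three-tissue brain ellipsoid (cortical shell 0.45, white-matter interior
0.70, central ventricle 0.15) contains two bent-ellipsoid hippocampi
(intensity 0.55, axis ratios 0.55 : 1.6 : 0.75, bend implemented as a
volume-preserving shear so the analytic volume is exact; the default target
is the 2650.2 mm³ mean training volume). Degradations: a smooth
multiplicative bias field (default relative amplitude 0.2), additive
Gaussian noise on foreground (sd 0.02) and a seeded rigid pose jitter
(±3 voxels, ±5°) applied analytically — masks are evaluated from the same
jittered geometry before any intensity degradation, so ground truth is
exact. The generator raises if the voxelized hippocampus volume deviates
more than 10% from the request (structure truncated by the grid).

**Cohorts** (`CohortSpec`): group sizes default to 145 CTRL / 217 MCI / 94
AD with ages 73±6 / 75±9 / 75±9 years truncated to [55, 95]. True volume =
V₀ + k(age − t₀) − Δ_group + subject effect, with V₀ = 3173 mm³,
k = −29.9 mm³/yr, Δ_MCI = 250 mm³, Δ_AD = 500 mm³, subject-effect sd
150 mm³; recorded volumes add per-scan measurement noise of 84.3/√2 mm³ so
the screening − repeat residual sd is 84.3 mm³ — tying the simulator to the
precision the pipeline is evaluated against. Longitudinal tables share the
true volume between screening and repeat and subtract group-specific annual
atrophy at 12/24 months (CTRL 29.9, MCI 60, AD 100 mm³/yr — the control rate
is the normal-aging slope; the MCI/AD rates are typical literature
magnitudes, chosen once).

What the phantoms do **not** emulate: anatomical shape variability beyond
volume and pose, Rician MRI noise, k-space artefacts, partial-volume decay at
tissue interfaces, or multi-modal contrasts. Passing tests therefore
demonstrate internal correctness and robustness of the machinery under
controlled conditions, not clinical-grade accuracy on real MRI. One subtlety
worth knowing: because MCI/AD groups are older and volume depends on age,
groups differ through normal aging even with zero atrophy offsets; null-case
tests match the age distributions to isolate the offset effect.

## Numerical conventions

- Axis order (x, y, z), 0-based voxel indices; VOI vectors and feature rows
  share one raster order (x fastest) so they stay index-aligned.
- Pearson correlation uses the one-pass product-moment form, clipped to
  [−1, 1]; constant vectors raise rather than returning NaN.
- Population variance in moment features (deterministic for tiny boxes);
  sample variance in cohort statistics (inferential context).
- Score maps are clipped to [0,1] after fusion; binarization is strict
  (score exactly equal to t stays background).
- All randomness flows from named integer seeds through
  `numpy.random.default_rng`; no global RNG state. Identical configuration
  and seeds reproduce CSV/JSON artifacts byte for byte (the run log's
  timings live in a separate `run_log_*.json`).

## Known limitations

- The registration is a lightweight stand-in: adequate for rigid-jittered
  phantoms, not a replacement for production registration tools on real
  brains (a pluggable external backend is the intended path there).
- Bias correction assumes a low-order multiplicative field and k separable
  intensity classes; pathological or very strong fields degrade it.
- The Eq.-style Bayesian threshold is sensitive to optimistic (S, s): nearly
  perfect classifiers push t high and bias volumes slightly low. This is a
  property of the method, visible in the phantom experiments.
- The Haralick set is the 5 canonical features rather than the full 13/14;
  the schema records the choice so it can be extended.
- Volumes are template-space; native-space volumetry would need the inverse
  warp applied to the mask, which is only exact for the affine part.
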