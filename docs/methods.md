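# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `petclust`.

## Phantom generator

**Geometry.** Each subject is a 64 × 64 × 160 voxel grid at 4 mm isotropic
spacing (axes: left–right, anterior–posterior, inferior–superior). The
skeleton is a stylized union of solids — vertebral column (cylinder),
cranial vault (ellipsoidal shell), two iliac blobs, proximal femora
(cylinders), and five elliptical rib rings — totalling ≈ 21 000 bone
voxels (≈ 1 340 cm³). Only two properties matter downstream and both are
exact: bone CT attenuation (default 400 HU) exceeds the 150 HU VOI
threshold everywhere, and soft tissue (40 HU) falls below it. Optional
distractor foci (high-HU single voxels away from the skeleton) exercise
the connected-component cleanup.

**Lesions.** A target total volume is converted to a voxel count
(rounded, hence exact to within half a voxel) and split across the
requested lesion count. Each lesion grows from a random bone seed voxel by
absorbing the nearest still-available bone voxels, so lesions are compact
blobs confined to the skeleton and the total planted volume is within one
voxel volume of the target by construction. Requests exceeding the
skeletal capacity raise an error stating the voxel deficit. PET values are
piecewise constant: `lesion_suv` in lesions (default 5.0), a diffuse bone
background (default 1.0) elsewhere in the skeleton, 0.5 in soft tissue —
all on the correct side of the 2.5 SUV threshold, so recovered MTV equals
planted volume up to the voxelization error.

**Cohorts.** Per-subject lesion burden is zero-inflated lognormal:
P(no focal disease) = 0.14, otherwise exp(N(log 33, 1.1²)) cm³ capped at
600 cm³ — median ≈ 33 cm³ with a long right tail, the shape of burden
distributions reported for newly diagnosed myeloma. Alternatively a
discrete set of burden levels can be planted (`burden_levels`), optionally
with per-level lesion SUV and per-level diffuse marrow uptake, which makes
it possible to construct strata that differ in image appearance but not in
hazard. Lesion count grows with burden (1 + Poisson(V/10), capped at 40),
so high-burden subjects look diffusely involved rather than dominated by
one giant blob — as multifocal skeletal disease does. Covariates emulate a
newly diagnosed cohort: age ~ N(62, 10²) clipped to 41–90, 54% male, stage
I/II/III ≈ 27/52/21%, 53% transplanted, induction regimen correlated with
transplant status.

**Survival.** PFS times are exponential given the linear predictor
`0.4·log(1 + V) − 0.85·ASCT` over a baseline hazard of 4 × 10⁻⁴/day —
the simplest model satisfying proportional hazards, with a transplant
effect of HR ≈ 0.43 and burden effects in the range reported for high-MTV
disease. Censoring is an independent exponential (3 × 10⁻⁴/day) plus an
administrative cap at 3272 days; observed event fractions land near 75–85%.
Because ASCT is in the generating hazard, calibration checks of the burden
coefficient must adjust for it: a univariate fit is attenuated by
omitted-covariate non-collapsibility, which is a property of the Cox
model, not a bug.

**What the phantoms do not emulate:** scanner physics (noise texture,
point-spread, attenuation artifacts), anatomical realism, osteolytic
lesions below 150 HU, extramedullary disease, and intra-lesion SUV
heterogeneity. Tests passing on phantoms therefore validate the *software
contracts* (thresholds, bookkeeping, statistics, reproducibility), not
clinical performance on real images.

## Bone VOI

The VOI is `HU > 150` (strict, reading "above" as exclusive) followed by
removal of connected components smaller than 20 voxels at 26-connectivity
— an automated stand-in for the manual exclusion of calcifications and
foreign material that a physician would perform; both parameters are
config-exposed precisely because the manual rule they replace is not
formalizable. Cleanup only removes voxels. Masked PET volumes carry NaN
outside the VOI so an SUV of exactly 0 inside bone is never confused with
"excluded".

## Conventional parameters

MTV counts in-mask voxels with SUV ≥ 2.5 (inclusive — the PET convention
for a "threshold of 2.5") times the voxel volume from the grid spacing
(anisotropic spacing supported). TLG multiplies MTV by the mean SUV of
exactly those voxels. Two means are reported and labeled distinctly:
`suv_mean_voi` (whole VOI) and `suv_mean_lesion` (supra-threshold voxels,
the one inside TLG); reporting both resolves the ambiguity of which mean a
"TLG" refers to.

## MIP construction

Anterior projection = voxelwise maximum along the AP axis with excluded
voxels as 0; rows run superior → inferior. The projection is cropped to
the bounding box of nonzero pixels (config-exposed; `crop=False`
available), resized to 64 × 128 (width × height) by bilinear
interpolation without aspect-ratio preservation, then divided by a fixed
SUV cap (default 10.0) and clipped to [0, 1]. A *fixed* cap rather than
per-image max-scaling is deliberate: the decoder ends in a sigmoid so
inputs must live in [0, 1], but between-subject intensity differences are
exactly the signal the clusters should reflect and per-image scaling would
erase them.

## Autoencoder

Encoder: three stages of 3×3 convolution (16, 20, 24 filters) + ReLU +
2×2 max-pool; decoder: 3×3 convolutions with 24, 20, 16, 1 filters, 2×2
nearest-neighbor up-sampling after the first three, ReLU on the first
three and sigmoid on the last. Same padding throughout — forced by
arithmetic, since three 2×2 poolings must take 128 × 64 to 16 × 8 so that
the 24-channel bottleneck flattens to exactly 3072 values. Anything else
is rejected at construction time with the offending shape.

Training: Adam at learning rate 0.01, batch size 4, 100 epochs by
default, per-pixel binary cross-entropy (natural for sigmoid outputs on
[0, 1] images; MSE available). The 1:1 train/test split (sizes differ by
at most one) is for monitoring only; features are extracted for every
subject from the same trained model. Weight initialization is seeded He;
data order is reshuffled each epoch from the same seeded generator, so
training is bit-reproducible. The implementation is plain NumPy — im2col
convolutions lowered to BLAS matrix products, with analytic gradients
verified against central finite differences in the test suite.

## Clustering

Both routes use k-means with k-means++ initialization, 10 restarts and a
fixed seed, k = 3, max 300 iterations.

**Unsupervised.** Features are mean-centered but *not* scaled to unit
variance: bottleneck channels are co-trained and share a natural scale,
and per-feature variance normalization amplifies near-dead units until
their noise buries the burden signal (measured directly on tiered
phantoms: the first principal component of raw features correlates ≈ 0.8
with log-burden, while clusters on standardized features stop tracking
burden at all).

**Supervised (outcome-weighted).** Within each of 10 × 3 cross-validation
folds: (1) a vectorized Newton solver fits a univariate Cox model (Breslow
ties) to every standardized feature on the training subjects at once —
thousands of lifelines fits would be prohibitively slow, and the solver is
cross-checked against lifelines in the tests; (2) each feature is weighted
by `max(|β|/SE − 2, 0)`, the soft-thresholded Wald statistic. Weighting by
evidence rather than raw |β| matters twice over: the aggregated sampling
noise of thousands of null coefficients would otherwise dominate the
distances, and near-separating sparse features (whose |β| explodes while
its SE explodes with it) would otherwise hijack the embedding; (3)
weighted features are embedded by classical MDS of squared-Euclidean
distances, computed as PCA of the weighted matrix (the two are identical
here) with up to 10 components; (4) k-means on the training embedding;
(5) held-out subjects go to the nearest training centroid. Each
round × fold yields a full-cohort labeling; labelings are aligned to the
first by Hungarian matching of the label contingency table and merged by
per-subject majority vote (ties to the lower label). The threshold 2 is
the conventional two-sigma evidence scale, and recovery of planted
structure is flat across thresholds 2–3 and 2–10 components.

**Ordering.** Clusters are renamed A, B, C by ascending within-cluster
mean MTV (ties by raw label index), so C is always the highest-burden
group; renaming never moves a subject.

**PCA visualization** uses mean-centered projections with component
variances in nonincreasing order; a constant feature matrix is rejected.

## Survival analysis

PFS events are relapse/progression/death; censoring otherwise. Cox models
are partial-likelihood fits (lifelines) with Efron tie handling and Wald
95% CIs; categorical covariates are dummy-coded against explicit reference
levels. In multivariate mode the interface enforces *at most one* of
{unsupervised cluster, supervised cluster, MTV group} per model — they are
collinear burden readouts — and the pipeline excludes chemotherapy regimen
from multivariate models because the generator (like real cohorts) makes
it collinear with transplant status.

**Cutpoints.** The MTV strata come from maximally selected log-rank
statistics: every midpoint between adjacent distinct marker values is a
candidate, splits leaving a group below `min_prop = 0.1` of the cohort are
excluded, and the cut maximizing |U/√V| wins (U, V from the hypergeometric
per-event-time decomposition). The search is exhaustive over candidates,
so it agrees with brute force by construction — the tests verify this
against an independent textbook implementation. Two boundaries (a
three-way low/moderate/high split) are produced sequentially: best single
cut, then the same search inside the larger stratum; an exhaustive joint
two-cut search scored by the three-group log-rank chi-square is exposed
for comparison (`strategy="joint"`). The sequential default is the
pragmatic reading of deriving two boundaries from a single-cut tool.

**Tertiles** cut at the 33.3rd/66.7th percentiles with groups
`v < c1`, `c1 ≤ v < c2`, `v ≥ c2`; heavy ties simply follow the
percentile rule and may be unequal.

**Cluster-parameter comparisons** use Kruskal–Wallis per parameter with
pairwise Mann–Whitney tests corrected by Benjamini–Hochberg. Values are
log1p-transformed before testing: MTV and TLG can be exactly 0, so a plain
logarithm is undefined, and since both tests are rank-based the monotone
transform changes nothing but keeps reported effect scales aligned with
how these skewed parameters are displayed. α = 0.05, two-sided,
throughout.

## Pipeline and reproducibility

`run_pipeline` sequences phantom → VOI → parameters → MIP → training →
encoding → both clusterings → ordering → survival tables, writing masks
(NIfTI), tables (CSV), images (PNG + `.npy`), the model (`.npz`) and a
manifest (config SHA-256 hash, seeds, versions). One global seed fans out
by fixed offsets (cohort +0, autoencoder +1, k-means +2, supervised +3),
so stage reruns and whole-pipeline reruns are reproducible; the test suite
asserts byte-identical output tables across reruns. Any stage failure is
re-raised with the stage name and subject id.

## Problem sizes used in tests

The end-to-end checks run a 60-subject cohort with training shortened to
40 epochs — on these piecewise-constant phantoms the reconstruction loss
plateaus well before that, and the checks target reproducibility and
survival structure, not reconstruction quality. Statistical calibration
checks use n = 300–500 records (no volumes generated) over 40–50 seeds;
planted-cluster recovery uses n = 150 subjects × 3001 features. Defaults
for real use remain 100 epochs.

## Known limitations

- The phantom's simplicity means image-feature clusters reduce to burden,
  diffuse-uptake and intensity patterns; texture-driven cluster structure
  cannot be studied with it.
- The supervised route's weight rule (soft-thresholded Wald statistics) is
  one concrete realization of outcome-weighted clustering; other shrinkage
  choices are plausible and the threshold is config-exposed.
- No partial-volume correction, percentage-of-SUVmax thresholds, DICOM
  network retrieval, or 3-D autoencoder inputs.
- Proportional-hazards diagnostics are not run automatically; the
  generator satisfies PH by construction, real data may not.
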