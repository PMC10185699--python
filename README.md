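# petclust

Skeletal FDG PET/CT burden quantification, autoencoder feature extraction,
and survival-validated clustering — with a synthetic phantom-cohort
generator so the whole pipeline runs and is testable without any patient
data.

## The problem

In multiple myeloma, whole-body FDG PET/CT measures skeletal tumor burden.
Conventional readouts are computed inside a bone volume-of-interest (VOI)
segmented from CT as all voxels with attenuation above 150 HU:

- **SUVmax / SUVmean** — maximum and mean standardized uptake value over
  the VOI, where SUV = activity × body weight / injected dose;
- **MTV** (metabolic tumor volume) — total volume of VOI voxels with
  SUV ≥ 2.5, in cm³;
- **TLG** (total lesion glycolysis) — MTV × mean SUV of those
  supra-threshold voxels.

Beyond scalar burden metrics, the package compresses each subject's
anterior maximum-intensity projection (MIP, resized to 64 × 128 pixels and
normalized to [0, 1]) with a convolutional autoencoder: three 3×3
convolution + 2×2 max-pooling stages (16, 20, 24 filters) encode the image
into an 8 × 16 × 24 bottleneck — **3072 features** — and a mirrored decoder
(24, 20, 16, 1 filters, 2×2 up-sampling, sigmoid output) is trained to
reconstruct the input (Adam, lr 0.01, batch size 4, 100 epochs, 1:1
train/test split for monitoring). Subjects are then grouped three ways
into clusters **A, B, C** (renamed in ascending order of mean MTV):

- **unsupervised** — k-means (k = 3, max 300 iterations) on the features;
- **supervised** — outcome-weighted clustering: each standardized feature
  is weighted by the soft-thresholded Wald statistic of its univariate Cox
  association with progression-free survival (PFS), subjects are embedded
  by classical MDS of the weighted distances and k-means-clustered inside
  10 rounds of 3-fold cross-validation, and the fold labelings are merged
  by Hungarian matching + majority vote.

Clusters and MTV strata (cut at maximally selected log-rank cutpoints) are
validated against PFS with Kaplan–Meier curves, log-rank tests, univariate
and multivariate Cox models (one imaging variable at a time, because
cluster labels and MTV strata are collinear burden readouts), and
Kruskal–Wallis comparisons of the conventional parameters across clusters.

Because no real images ship with the package, a `phantom` module generates
stylized whole-body CT/PET pairs — a high-HU skeleton, focal lesions of
exactly controlled total volume and SUV — and cohorts whose PFS times
follow a proportional-hazards model with hazard increasing in lesion
burden. Every stage of the pipeline is tested against this ground truth.

## Worked example

```python
from petclust import (PhantomSpec, generate_phantom, extract_bone_mask,
                      conventional_params)

ph = generate_phantom(PhantomSpec(lesion_volume_cm3=30, lesion_suv=5, seed=1))
mask = extract_bone_mask(ph.volumes.ct)          # HU > 150, cleaned
p = conventional_params(ph.volumes.suv, mask, ph.volumes.voxel_volume_cm3)
for k, v in p.as_dict().items():
    print(f"{k}: {v:.3f}")
```

prints

```
suv_max: 5.000
suv_mean_voi: 1.090
suv_mean_lesion: 5.000
mtv_cm3: 30.016
tlg: 150.080
```

The planted 30 cm³ lesion burden is recovered to within one 0.064 cm³
voxel (30.016 cm³); SUVmax equals the planted lesion SUV; TLG = MTV × mean
supra-threshold SUV = 30.016 × 5.

The full pipeline runs from the shell:

```bash
petclust run-all --config config.yaml --out results/
```

with, e.g.,

```yaml
cohort: {n_subjects: 20}
train:  {epochs: 20}
seed: 1
```

which prints a run summary such as

```
completed: 20 subjects -> results/
MTV cutpoints: [0.9, 63.2] cm3
unsupervised cluster sizes: {'A': 1, 'B': 18, 'C': 1}
supervised cluster sizes: {'A': 17, 'B': 1, 'C': 2}
```

and writes bone masks (NIfTI), the parameter table, MIPs (PNG + `.npy`),
the trained model, the 3072-column feature matrix, both cluster labelings,
PCA plots, KM plots and Cox tables, plus a manifest with the configuration
hash and per-stage seeds. Stage-by-stage subcommands (`phantom`, `mask`,
`params`, `mip`, `train`, `encode`, `cluster`, `survive`) consume each
other's files for piecemeal runs.

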