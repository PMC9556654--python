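# dcnet

Voxel-wise **degree centrality** (DC) analysis of resting-state fMRI for
case/control studies, with a synthetic-cohort generator that makes every
stage testable end to end.

Degree centrality treats every voxel as a node in a whole-brain
functional graph: a voxel's DC is the number of other gray-matter voxels
whose BOLD time series correlate with it above a threshold,

    DC(i) = #{ j != i : r_ij > 0.25 },

z-scored within the gray-matter mask and smoothed (6 mm FWHM). Group
differences in standardized DC are tested voxel-wise with an ANCOVA
(group + age + sex), corrected at cluster level by Gaussian random-field
theory or by a Freedman-Lane permutation test. Mean DC inside the
surviving clusters then feeds (a) Pearson / multiple-regression
correlation with clinical scores (Bonferroni-corrected) and (b) an
RBF-kernel SVM that discriminates patients from controls with
grid-searched (C, gamma) and leave-one-out cross-validated accuracy,
sensitivity, and specificity.

The package is aimed at methodologists who want a transparent, tested
re-implementation of this common DC-plus-SVM protocol, and at anyone who
needs a controllable synthetic resting-state cohort: two groups with
configurable hub regions whose connectivity differs by a known sign and
magnitude, plus realistic motion traces, confound masks, and a clinical
metadata table.

## Worked example

```python
import numpy as np
from dcnet import (CohortSpec, generate_cohort, dc_pipeline,
                   make_group_design, fit_voxelwise_glm, grf_cluster_correct)

spec = CohortSpec(n_per_group=30, grid_shape=(18, 18, 18), n_timepoints=212, seed=1)
bolds, motion, mask, cohort, truth = generate_cohort(spec)

dc_maps = [dc_pipeline(b, mask) for b in bolds]          # per-subject DC
design = make_group_design(cohort)                        # group + age + sex
stat = fit_voxelwise_glm(dc_maps, design, mask)           # voxel-wise ANCOVA
clusters = grf_cluster_correct(stat, mask, voxel_p=0.01)  # GRF cluster correction
print(clusters[["peak_x_mm", "peak_y_mm", "peak_z_mm", "n_voxels", "peak_t", "sign"]])
```

Output (seed 1):

```
   peak_x_mm  peak_y_mm  peak_z_mm  n_voxels     peak_t      sign
0       39.0       27.0       12.0       114 -15.359686  decrease
1       12.0       39.0       39.0       126 -14.772118  decrease
2       39.0       39.0       39.0        85 -12.495800  decrease
3       15.0       12.0        9.0       122  11.695323  increase
4       39.0       15.0       39.0        97   9.196372  increase
5       27.0       42.0       12.0        97   8.299498  increase
```

The generator planted six hub regions — three with increased and three
with decreased patient connectivity at effect magnitude 0.5 — and the
pipeline recovers exactly three `increase` and three `decrease`
clusters, each centered on a planted hub (peak coordinates are world mm
from the 3 mm affine). `truth.region_mask(i)` gives the planted voxel
sets for quantitative recovery scoring.

Confusion-metric arithmetic is exposed directly: with 70 of 76 patients
and 66 of 67 controls classified correctly,

```python
>>> from dcnet import confusion_metrics
>>> confusion_metrics(tp=70, fn=6, tn=66, fp=1)
(95.1, 92.1, 98.5)
```

i.e. 95.1% accuracy (136/143), 92.1% sensitivity, 98.5% specificity.

## Command line

```bash
dcnet run --config config.yaml --out results/      # full pipeline on a simulated cohort
dcnet simulate --out sim/ --seed 3                 # cohort only
dcnet preprocess --bold sub.nii.gz --motion sub_motion.txt --out clean.nii.gz
dcnet dc --bold clean.nii.gz --mask gm.nii.gz --rthr 0.25 --fwhm 6 --out dc/
dcnet infer --dc-dir dc/ --cohort cohort.csv --mask gm.nii.gz --method grf --out clusters.csv
dcnet classify --features region_features.csv --cv loo --out svm.csv
```

Every threshold defaults to the standard protocol values (discard 5
volumes; exclude > 2 mm / > 2 degree movers; 0.01-0.1 Hz band; r > 0.25;
cluster-forming voxel p < 0.01). `docs/methods.md` documents the models,
defaults, and design decisions.

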