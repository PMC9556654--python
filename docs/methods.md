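# Methods

`dcnet` implements a voxel-wise degree-centrality (DC) analysis of
resting-state fMRI for a two-group (patient vs. control) design, together
with a synthetic-cohort generator that makes every stage verifiable at
desk scale. This note records the models, the parameter choices that
matter, and the numerical decisions taken where the protocol left the
design open.

## Degree centrality

For each subject, every in-mask voxel's time series is correlated
(Pearson) with every other in-mask voxel's. The correlation matrix is
binarized at `r > 0.25` (strict inequality; ties at exactly 0.25 and all
negative correlations are discarded) and each voxel's suprathreshold
connections are counted:

    DC(i) = #{ j != i : r_ij > 0.25 }

The count map is z-scored within the analysis mask,
`Z(i) = (DC(i) - mean) / sd`, and smoothed with a 6 mm FWHM Gaussian
kernel. A Fisher-weighted variant (`method="fisher_weighted"`) sums
`atanh(r_ij)` over the same suprathreshold edges before z-scoring; the
binarized count is the default, and the choice is recorded in every
map's JSON sidecar. Correlations are clamped to [-1, 1] before
thresholding or `atanh`, which guards the transform against overflow on
duplicated series.

A whole-brain gray-matter mask at 3 mm has ~5e4 voxels, so the V x V
correlation matrix is never materialized: series are mean-centered and
norm-scaled once, and correlation blocks are streamed in row chunks
(`chunk_size`). The result is exactly independent of the chunking, which
the tests verify against a dense brute-force oracle up to 2,000 voxels.

## Preprocessing

Fixed order: discard initial volumes (default 5) -> motion QC ->
nuisance regression -> bandpass -> optional smoothing.

* **Motion QC** excludes a subject iff any translation column exceeds
  2 mm or any rotation column exceeds 2 degrees in absolute value,
  strictly. Per-column maxima are used, not framewise displacement.
* **Nuisance regression** is a single OLS per voxel against intercept,
  linear trend (the detrending step, folded in because it is
  mathematically equivalent), white-matter and ventricle mean signals,
  and the six motion parameters. Residuals are orthogonal to every
  confound column; rank-deficient confounds fall back to the
  pseudo-inverse with a warning.
* **Bandpass** (0.01-0.1 Hz) is a zero-phase frequency-domain filter
  with a raised-cosine roll-off of 10% of each band edge. Zero phase
  avoids time shifts that would distort correlations; the roll-off keeps
  pass-band amplitudes within 5% while rejecting components an octave
  outside the band by more than 90%.
* **Smoothing** is plain separable Gaussian convolution with reflect
  padding (`sigma = fwhm / (2 sqrt(2 ln 2))` per axis in voxel units,
  kernel truncated at 6 sigma); no masked renormalization is applied at
  this stage, so the operation is deterministic and linear. Masked
  operations happen at DC standardization instead.

The emulated protocol smooths at 8 mm before DC and again at 6 mm after.
Both switches are independent. On synthetic data the 8 mm pre-smoothing
step substantially dilutes binarized-degree contrast (it inflates local
correlations toward 1 everywhere, so the threshold loses selectivity) —
a known concern with smoothing before graph construction. The recovery
analyses below therefore characterize the DC -> inference -> classify
chain on generator output directly; the preprocessing stage is verified
by its own oracle contracts (filter gain, OLS residuals, kernel shape,
QC rule).

## Group inference

Per voxel, standardized DC is regressed on a patient/control indicator,
covariates (age and sex by default — the matched demographic variables;
the covariate set is configurable and logged), and an intercept. The
group contrast's t-statistic forms the statistic image; with no
covariates it reduces exactly to the pooled two-sample t. Clusters form
at the two-tailed t quantile of `voxel_p = 0.01`, separately per sign,
with 26-connectivity (6/18 available).

**Random-field correction.** Residual smoothness is estimated with the
normalized-residual gradient estimator (`FWHM_i = sqrt(4 ln 2 /
var(grad_i u))`); resel counts R0..R3 come from the mask's
point/edge/face/cube counts. Expected cluster count per tail is
`E[m] = sum_d R_d rho_d(u)` with the t-field Euler-characteristic
densities; expected cluster extent is `E[N] = V * P(T > u) / E[m]`, and
a cluster of k voxels gets `p_unc = exp(-beta k^(2/3))` with
`beta = (Gamma(5/2)/E[N])^(2/3)` (the Poisson-clumping approximation).
The family-wise p uses both tails: `p_corr = 1 - exp(-2 E[m] p_unc)`.
On 200 null synthetic cohorts this controls the family-wise error at or
below nominal (measured 0.04 at alpha = 0.05).

**Permutation alternative.** Freedman-Lane: covariate effects are fixed
by permuting reduced-model residuals; the null statistic is the maximal
suprathreshold cluster extent over both tails; corrected p-values are
rank-based with +1 smoothing, hence valid under exchangeability. On the
same 200-cohort null suite the empirical FWER is statistically
indistinguishable from alpha.

The minimum reportable cluster extent (default 50 voxels) is applied at
the reporting stage, not inside the correction, so calibration studies
see the uncensored cluster stream.

## Clinical correlation and classification

Surviving clusters define regions; the per-subject feature is the mean
standardized DC within each region. Pearson correlations (or a joint
multiple-factor regression per region) relate features to clinical
variables, Bonferroni- or BH-corrected across the full region x variable
family. Severity (HRSD-17) and illness duration are analyzed on the
patient subset — duration does not exist for controls, and severity
questions concern the patient population.

Classification is an RBF-kernel SVM on region features. A (C, gamma)
grid — powers of two from 2^-10 to 2^10 by default, the LIBSVM grid-tool
convention — is searched exhaustively by cross-validated accuracy
(leave-one-out by default, standard at this sample size; stratified
k-fold available). Ties prefer smaller C, then smaller gamma. Feature
standardization is fit inside each training fold only. Reports carry
integer confusion counts, so accuracy/sensitivity/specificity are exact
fractions. Because selecting the (C, gamma) maximizer makes the reported
CV accuracy the maximum of several noisy estimates, null-data accuracies
sit slightly above 0.5 on average; this selection optimism is inherent
to the protocol being modeled (regions from an all-subjects contrast,
CV on the same subjects) and is why the package also provides a
`nested` protocol that redoes cluster selection inside every training
fold for an unbiased estimate. Both are reported, neither silently
substituted.

## Synthetic cohort generator

Per subject and voxel:

    bold(v,t) = offset + A * sum_k L[s,k] a_k(v) z_k(t) + noise(v,t)

* `z_k` are unit-variance latent time courses: AR(1) innovations
  (coefficient 0.3) band-limited to 0.01-0.1 Hz, because real
  resting-state network fluctuations concentrate below ~0.1 Hz — this
  is what makes the bandpass stage signal-preserving. Five background
  networks occupy random spheres; each hub region gets a dedicated
  latent so planted effects in different hubs cannot interfere.
* `a_k(v)` is a Gaussian-tapered amplitude on the network's sphere
  (taper sigma = radius/1.5). The taper spreads pairwise correlations
  across the binarization threshold, so binary degree responds smoothly
  to amplitude changes.
* The default signal amplitude `A = 0.8` (noise sd 1) places typical
  within-network correlations just around the 0.25 threshold; this is
  what gives the planted effect a graded, recoverable degree response in
  both directions.
* Hub voxels in the patient group have their amplitude scaled by
  `(1 + sign * magnitude)`; magnitude 0 makes the groups exchangeable
  by construction (the basis of the permutation calibration).
* Noise is white Gaussian smoothed spatially at 6 mm FWHM — matching
  the smoothness assumptions of the random-field correction — and
  rescaled to unit sd. Subject loadings `L ~ N(1, 0.1)`.
* Metadata are drawn from truncated normals matching the emulated
  cohort: patient HRSD-17 ~ N(22.9, 4.3) truncated at >= 17 (the
  eligibility floor), controls ~ N(8.7, 5.8) truncated at >= 0, ages
  14-18, ~62% male, illness duration < 12 months, absent for controls.
  Nothing couples DC to any clinical score, so clinical correlations are
  null by construction.
* All randomness derives from one integer seed through fixed per-subject
  substreams; identical specs give bit-identical cohorts.

The generator does **not** model hemodynamic response shape,
physiological (cardiac/respiratory) noise, scanner drift beyond a linear
trend, registration error, or multi-site effects. Passing tests
therefore demonstrate the correctness and calibration of the analysis
chain under idealized spatial structure — not robustness to real
acquisition artifacts.

## Problem sizes used in the test and acceptance runs

Chosen as the smallest sizes at which each property is stably
measurable: null calibration uses 200 cohorts of 20 + 20 subjects on a
12^3 grid with 60 volumes; planted-region recovery uses 30 + 30
subjects on an 18^3 grid with the full 212 volumes (six hubs, magnitude
0.5; the 18^3 grid keeps same-sign hubs >= 9 voxels apart so their
clusters stay disjoint); classifier studies use 20 + 20 subjects on
12^3 grids. The DC oracle comparison covers random instances up to
2,000 mask voxels.

## Known limitations

* The RFT cluster p uses the standard approximations (Poisson clumping,
  stationary smoothness); on very small grids or near-voxel-size
  smoothness it is approximate — the permutation route is the reference
  when they disagree.
* The generator's planted effect acts through connectivity amplitude;
  it does not emulate regional signal loss, vascular confounds, or
  group differences in motion.
* Anatomical labeling of clusters (which real studies report) is out of
  scope; clusters are identified by coordinates and by overlap with the
  generator's ground truth.
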