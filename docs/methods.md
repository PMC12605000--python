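# Methods

`habitatrad` implements a subregion ("habitat") MRI radiomics analysis for
predicting a binary molecular label from spinal-metastasis lesions imaged in
two MRI sequences (T1W-like and T2FS-like). This note documents the model
and procedure, the synthetic cohorts the package is exercised on, the
numerical choices, and what the tests do and do not demonstrate.

## Intratumoral partitioning

Each lesion is partitioned in three steps, per sequence:

1. **Local-entropy mapping.** For every lesion voxel, the Shannon entropy
   H = −Σ_b p_b log2 p_b of the intensity histogram inside a 9×9 in-plane
   window (stride 1) is computed. The window is clipped to the lesion mask,
   so background never contaminates the histogram; histograms use 32
   equal-width bins spanning the ROI's min–max range (the bin count is a
   free choice — the procedure is insensitive in the tested range, and the
   value is configurable). Entropy windows are 2-D because slices are 4 mm
   apart while in-plane voxels are 1 mm: a 3-D window would be strongly
   anisotropic. Entropy and raw intensity are then Z-scored within each ROI.

2. **Patient-level superpixels.** k-means (k = 30, k-means++ with 10
   restarts to avoid local optima, fixed seed) clusters the per-voxel 2-D
   vectors (Z-intensity, Z-entropy) with the Euclidean metric. Each
   superpixel is summarised by the mean of its members' vectors. ROIs
   smaller than 30 voxels reduce k to the voxel count with a logged warning.

3. **Population-level clustering.** All training patients' superpixel
   summaries are pooled and clustered agglomeratively with Ward linkage.
   For every candidate K in [2, 10], the Calinski–Harabasz index
   CH = [B/(K−1)]/[W/(N−K)] and the mean Silhouette coefficient
   s(i) = (b(i)−a(i))/max(a(i), b(i)) are evaluated; K* maximises the mean
   Silhouette, with ties broken by the higher CH (the two indices are
   standard, the combination rule is this package's choice). Cluster
   centroids are stored, ordered by ascending mean Z-entropy, and define the
   habitat names: S1 is the lowest-entropy ("marginal") cluster and the
   highest-entropy cluster is the "inner" habitat (S2 when K* = 2).

Patients outside the fitting population (internal/external validation)
receive habitat labels by nearest population centroid; this avoids refitting
and keeps held-out data out of the clustering. Sequences are partitioned
independently, and S1/S2 are matched across sequences by the entropy
ordering.

## Feature extraction

Images are Z-score normalised over the lesion and passed through a filter
bank (Laplacian-of-Gaussian at σ ∈ {3, 5} mm, an undecimated coif1 wavelet
subband, square, square root, logarithm, exponential, gradient magnitude,
and a 2-D rotation-invariant uniform LBP per slice; `lbp-3D-m2` is accepted
as an alias of the 2-D LBP and logged). For each patient × sequence ×
region (S1, S2, whole tumor) and each derived image, first-order statistics
and texture features are computed on gray levels discretized to a fixed bin
count (32, levels 1..N_g over the region range). Texture matrices use
distance-1 offsets with 26-connectivity in 3-D (an in-plane 2-D mode with
8-connectivity exists), and features are averaged over angles.

First-class implementations, each verified against an independent
brute-force enumeration on random small fixtures:

- **GLCM Inverse Variance** IV = Σ_{i≠j} p(i,j)/(i−j)² on the symmetric,
  normalized co-occurrence matrix;
- **GLCM MCC**, the square root of the second-largest eigenvalue of
  Q(i,j) = Σ_k p(i,k)p(j,k)/(p_x(i)p_y(k));
- **GLDM Dependence Non-Uniformity Normalized** (α = 0), with the
  dependence size of a voxel counted as itself plus its equal-level
  distance-1 neighbours;
- **GLSZM Small Area Emphasis**, zones being connected components of equal
  level (full 26-/8-connectivity by default; face connectivity available);
- **first-order 90th percentile** with linear (type-7) interpolation, the
  convention that the percentile features depend on;
- one representative each of the GLRLM (Short Run Emphasis) and NGTDM
  (Coarseness) families, for catalogue realism.

Regions smaller than 10 voxels are dropped with a logged reason. Shape
features are not computed on subregions (subregion shape is a clustering
artifact).

**Reproducibility (ICC) filtering.** Features are re-extracted after a
seeded 1-voxel morphological jitter of the mask — a stand-in for a second
reader, which synthetic data cannot supply — and a two-way mixed-effects,
absolute-agreement, single-measures ICC is computed per feature; features
with ICC > 0.80 are retained. The model form is recorded in every report.

## Batch harmonization

Scanner effects are removed with parametric empirical-Bayes ComBat under
the location-scale model x = α + Xβ + γ_batch + δ_batch·ε, with a normal
prior on the per-batch locations γ and an inverse-gamma prior on the scales
δ² across features, solved by the standard iterative conditional means.
Biological covariates (the class label) are estimated jointly and preserved.
The model is fitted on training rows only and applied frozen to held-out
rows; unknown batch ids are a hard error. The implementation agrees with
`sva::ComBat` to within 0.3% of the data SD on identical input (tested via
Rscript).

One property worth knowing: when every feature carries the *same*
standardized batch shift, the empirical-Bayes prior across features is
nearly degenerate and shrinkage re-injects roughly half of the sampling
noise of the batch means, leaving residual per-feature gaps of ~0.05 SD at
n = 100/batch — the reference implementation behaves identically. With
realistically heterogeneous feature scales the prior is wide, shrinkage is
light, and residual gaps are ~0.01–0.03 SD. The simulation tests therefore
give features heterogeneous scales.

A no-harmonization path is first-class (`harmonize: none`, the default),
since ICC filtering alone is a legitimate robustness strategy and
harmonization does not always help; the config records which path ran.

## Signature construction

Selection is leakage-safe by construction: every selection input —
screening, standardization, the LASSO path and its penalty choice — is
computed from training rows only, and inside nested cross-validation from
the outer-training fold only.

1. **Screen.** Two-sided Mann–Whitney U per feature; retain p < 0.05
   (exact p for small samples, normal approximation otherwise; constant
   features get p = 1). No multiplicity correction at this stage by
   default; a Benjamini–Hochberg switch exists.
2. **LASSO.** L1-penalized logistic regression over a 50-point
   log-spaced grid from λ_max (the smallest penalty that zeroes all
   coefficients) down three decades; λ is chosen by minimum inner five-fold
   cross-validated binomial deviance ("lambda.min"; the 1-SE rule is the
   obvious alternative and the choice is recorded). Features are
   standardized with training means/SDs, applied frozen to validation rows.
3. **Signature.** The radiomics signature is RS(x) = Σ_f w_f z_f + b with
   the LASSO coefficients as weights on standardized features; an
   unpenalized 1-D logistic layer maps RS to a probability, and the
   training-split Youden cutoff is stored with the model. Perfect
   separation is flagged but the model is still emitted.
4. **Nested CV.** Outer stratified five-fold split; screening + LASSO per
   outer-training fold; pooled outer-fold predictions give the honest
   performance estimate; the deployable model is refit on the full training
   split.
5. **Fusion.** The best subregion per sequence (by training AUC of the
   subregion signatures) contributes its RS; the multi-sequence regional
   fusion model is a logistic regression on the two parent RS scores (a
   tiny L2 ridge, C = 1e6, keeps collinear parents solvable). A
   whole-tumor two-sequence combination is built the same way for
   comparison.

## Evaluation

AUC uses the Mann–Whitney pair-counting identity (ties count ½) with a
DeLong-variance confidence interval; correlated models are compared with
the DeLong test via placement values. The operating cutoff maximises the
Youden index J = SEN+SPE−1 over midpoints of adjacent distinct scores
(ties break toward higher specificity) on the training split and is frozen
for the validation splits (per-split cutoffs are a config option, default
off). AUPRC is the step-interpolated precision–recall area with a
percentile bootstrap CI (B = 2000, seeded). Calibration uses five quantile
bins plus a logistic recalibration intercept/slope. Decision curves report
NB(pt) = TP/N − (FP/N)·pt/(1−pt) on a 0.01–0.60 grid against treat-all and
treat-none. Waterfall data, per-split clinical ("Table-1 style") summaries
(Mann–Whitney for continuous, chi-square with Yates continuity correction
for 2×2 categorical, Fisher fallback flagged when an expected cell < 1) and
a consolidated model × split report complete the stage.

## Explanations

For models whose margin is linear in their features — both the single-
sequence signatures and the fusion model (which is linear in the underlying
features through the chain rule, exactly) — Shapley attributions have the
closed form φ_f(x) = w_f (x_f − E_bg[x_f]) on the margin (logit) scale with
the training split as background; local accuracy Σφ + base = margin holds to
machine precision, which is why the margin scale is used. Bar (mean |φ|)
and beeswarm summaries, a Spearman feature-correlation heatmap and a
Ward-ordered patient × feature heatmap are produced.

## Synthetic cohorts

No patient data are distributable, so the generator is first-class, tested
code that defines the study conditions. Each patient carries one
near-cylindrical ellipsoidal lesion (in-plane radius 20–28% of a 96×96
grid, 4 slices, 1×1×4 mm spacing — sizes representative of spinal
metastases at ~1 mm in-plane resolution) with a concentric inner habitat
(inner/outer semi-axis ratio 0.50–0.62, so the marginal shell stays thicker
than the entropy window's half-extent; a scattered-habitat mode exists for
robustness tests). Intensities are spatially correlated Gaussian fields:
white noise smoothed in-plane with habitat-specific correlation length
(marginal 1.4 voxels; inner 1.4/(1+`entropy_contrast`)) and amplitude
(inner amplitude grows with `entropy_contrast`, so roughness and histogram
width both raise the core's local entropy). The inner habitat sits
`habitat_contrast` voxel-SDs above the margin, and the two tissues blend
over ~1 voxel (partial volume) rather than meeting at a step edge — a step
would create spuriously high-entropy bimodal windows at the interface.
Defaults (`habitat_contrast` 3.0, `entropy_contrast` 2.5) give habitat
separations comparable to published habitat-imaging boxplots, i.e. largely
non-overlapping interquartile ranges.

Label-positive patients receive a perturbation of the **inner-habitat
texture only**: a slow multiplicative modulation field makes the core
patchy (nonuniform local variance) while a global renormalisation keeps the
ROI-level second moment unchanged — important because whole-ROI Z-score
normalisation would otherwise leak an ROI-level class signal into
marginal-region features. Between-patient biological variability comes
from lognormal jitter of the texture parameters (a patient-level factor
shared across sequences plus per-sequence jitter), without which any
consistent class effect would be perfectly separable at the patient level.
The default `class_effect` of 0.75 places the inner-habitat signature's
training AUC around 0.95–1.0, the marginal signature around 0.75–0.9 (weak
residual signal reaches S1 through the partial-volume ring and the entropy
window's smear across the interface — qualitatively matching the real
study, where marginal-region models also retained some discrimination), and
the two-sequence fusion at or above the better parent.

Scanner batches apply an additive shift and multiplicative scale to
intensities after class effects (the location-scale family ComBat removes);
the last batch plays the external center, and the remaining patients are
split train:internal at 2:1 stratified by label. The clinical table (age,
gender, smoking, PS score, CEA, CYFRA, NSE) mimics the marginal
distributions of a typical EGFR-mutant NSCLC cohort, with smoking
prevalence 45% in label-positive vs 10% in label-negative patients.

What the generator does **not** emulate: bone anatomy, pulse-sequence
physics, DICOM/scanner artifacts, reader variability (the ICC stage uses
seeded mask jitter instead), lesion multiplicity, and any genuine
biological link between texture and mutation status. Passing tests
demonstrate that the pipeline recovers *constructed* structure under
realistic noise — not that the radiomic signal exists in real patients.

## Problem sizes and numerical choices

- Multi-seed experiments use 40-patient cohorts; the test suite runs 20
  cohort replicates and the acceptance script 12 — enough to estimate the
  recovery/ordering rates it reports while keeping a full run comfortably
  reproducible on a laptop. The ordering experiment uses the gradient
  filter bank and the S1/S2 regions only, and fits signatures on the whole
  cohort (the quantity compared is the training AUC ordering).
- When screening or LASSO legitimately yields no signature for a region
  (typical for weak-signal marginal regions at small n), the region scores
  an AUC of 0.5 — "no model" — in ordering experiments.
- k-means and all CV splits are seeded; population clustering is
  order-invariant given the deterministic superpixel ordering (summaries
  sorted by mean entropy then intensity).
- Degenerate inputs: constant features (p = 1 in the screen, dropped in
  ICC, passed through in ComBat), single gray levels (MCC undefined,
  raised), empty habitats (rows dropped and logged), single batch
  (identity harmonization with warning), perfect separation (flagged).
- The silhouette of a singleton cluster is 0 (the standard convention).

## Known limitations

- The partial-volume blend means the realized core-to-shell intensity gap
  equals `habitat_contrast` only away from the interface; generator tests
  measure it between eroded cores.
- The entropy map inherits the 9×9 window's smear: voxels within ~4 voxels
  of the habitat interface carry mixed texture, which bounds achievable
  voxel-level partition agreement (≈0.8 Jaccard per habitat at default
  contrasts) and gives the marginal habitat its residual class signal.
- Empirical-Bayes shrinkage leaves a small residual batch gap when batch
  effects are homogeneous across features (see the harmonization section).
- The fusion model's advantage relies on partly independent per-sequence
  noise; with fully shared noise it degenerates to the better parent.
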