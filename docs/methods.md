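# Methods

This note documents the models, numerical choices and known limitations
of `wavefuse`. It is written for users who want to know exactly what the
pipeline computes and what its tests do and do not establish.

## Classification engine

Each modality is a subjects × features matrix. Classification is a
soft-margin linear SVM with C = 1 (no hyperparameter search; C is
configurable through every entry point). Features are mean-centered and
scaled to unit variance per column. By default (`scaling_fit_on="train"`)
the scaler is estimated on the n−1 training subjects of each LOOCV fold
and applied unchanged to the held-out row, so the held-out subject can
never influence its own fold's preprocessing; `scaling_fit_on="all"`
reproduces pipelines that scaled the whole sample once. Constant columns
pass through centered with a unit divisor.

Predictions use the SVM decision value with ties (exactly zero) resolved
to the positive class — the disorder/GAD class — which favors sensitivity
over specificity, the preferable error trade-off when a positive call
triggers further clinical attention. Balanced accuracy is exactly
(sensitivity + specificity)/2 on the aggregated fold-level confusion
counts, which protects against the unequal group sizes (24/19/14).

The per-fold primal weight vectors (oriented toward the positive class)
are averaged across folds; absolute values are taken only at the
region-summary stage, where each region's score is the mean |w| over its
feature columns and percentages renormalize those means to sum to 100.
Ranking ties break alphabetically for determinism.

For speed, the SVM is fit through scikit-learn's libsvm binding directly
(`wavefuse.classify.fit_linear_svm`); inputs are validated once per call
chain rather than once per fold, which matters when a full LOOCV runs
inside each of thousands of permutations. The wrapper is tested to agree
with `sklearn.svm.SVC(kernel="linear")` in both coefficients and decision
orientation on random datasets.

## Permutation tests

Single-modality significance re-runs the *entire* LOOCV (scaling and SVM
refit per fold) on each of B unstratified label permutations and uses the
add-one estimator p = (#{null ≥ observed} + 1)/(B + 1), which is never
exactly zero and is exchangeability-valid. Its type-I error at α = .05 is
verified over 100 no-effect cohorts (the acceptance suite).

The ensemble test instead keeps the fused predictions and per-fold
classifier weights fixed and rescoring them against permuted labels,
counting strictly better permutations: p = #{null > observed}/B. This is
orders of magnitude cheaper and mirrors how a fused result would be
assessed post hoc, but it has two caveats, both deliberate and kept: it
can return exactly 0 (a perfect observed prediction can never be strictly
beaten), and when the fused predictions are nearly constant all
permutations tie and p collapses to 0 spuriously. A full re-run scheme
(`scheme="full"`) is available as a sensitivity analysis.

## Null behavior of LOOCV — what "chance level" means here

On data with no class signal, leave-one-out SVM accuracy does not center
on 50%: removing the held-out subject tilts the training class balance
against that subject's class, producing the well-known pessimistic
(anti-correlation) bias of LOOCV on small samples. We measure mean null
balanced accuracies around 40–46% for single modalities at n = 16–24, and
weighted voting amplifies this slightly for the fused classifier. The
property tests therefore assert *no skill above chance* (mean null
accuracy within (33, 53) and permutation p not systematically small)
rather than an idealized 50% ± 5%. This is a property of the procedure —
shared by any faithful implementation — not an implementation artifact;
the permutation tests remain valid because their null distributions are
generated by the same procedure.

## WAVE

The weight-adjusted voting ensemble couples case weights q (difficulty)
and classifier weights p (quality) through q ∝ (1−X)p, p ∝ Xᵀq on the
binary performance matrix X. Substituting one relation into the other
shows that a joint fixed point satisfies p ∝ Xᵀ(1−X)p: p is the Perron
eigenvector of the nonnegative matrix A = Xᵀ(1−X). The naive alternating
update is exactly power iteration on A, which fails to converge whenever
−λ_max is also in A's spectrum (easy to hit with tiny matrices, e.g.
X = [[1,0],[1,0],[0,1]], whose A has eigenvalues ±√2). We therefore
iterate the damped map p ← (I + A)p with L1 normalization (uniform
start, tolerance 1e−10, max 1000 iterations), which has exactly the same
fixed points and converges for any nonnegative A; the result is verified
against a dense eigendecomposition to 1e−8 and beyond. When A is
nilpotent (some classifier is correct everywhere), convergence is
polynomial rather than geometric and the `converged` flag may stay false
at default settings while the ordering is already stable. All-correct and
all-wrong performance matrices carry no difficulty information and return
uniform weights with a `degenerate` flag.

Nested LOOCV guarantees outer-fold independence: the held-out subject
contributes neither to the inner performance matrix, nor to any scaler or
SVM fit, nor to the WAVE weights of its own fold — verified by a sentinel
test that corrupts the held-out subject with extreme values and checks
the fold's weights are bit-for-bit unaffected.

Fold-wise classifier weights are compared across modalities by paired
t-tests over outer folds; the choice of the paired t is a convention
(the underlying study reports significant weight differences without
naming a test), and zero-variance pairs are flagged rather than tested.

## Cortisol release feature

Total release is the area under the log concentration curve with respect
to the ground, by the trapezoid rule over the actual sampling minutes.
The log is natural by default: over a 100-minute window, group mean
log-AUC values in the 160–200 range correspond to concentrations of
e^1.6–e^2.0 ≈ 5–7 nmol/L, squarely in the physiological salivary range,
whereas base-10 would imply implausible levels; the base is configurable.
The time origin is the first sample (only intervals matter). Profiles
with any missing or nonpositive sample are excluded and the exclusion
propagates to every modality, since fusion requires complete data.
Agreement with a dense midpoint-rule integration of the interpolated
profile is within 0.5% for smooth profiles.

## Synthetic cohort generator

The generator emulates the *statistical* structure of a reference
clinical cohort, not its physics:

* **Group structure** — 24 controls, 19 GAD (12 with comorbid MD),
  14 MD-only by default; all sizes configurable.
* **Questionnaires** — per-group normal draws with the reference means
  and SDs, rounded and clipped to instrument ranges (PSWQ 16–80, BDI
  0–63, IUS-12 12–60, STAI-T 20–80). Clipping biases the realized mean
  wherever a bound sits within ~2 SD of the generative mean (materially
  only for the controls' BDI); the calibration tests check only cells
  where truncation is negligible.
* **Demographics** — category counts (sex, handedness, education,
  smoking, including one control with missing smoking status) are
  matched *exactly*, not sampled, so χ² statistics computed from a
  generated cohort reproduce the reference table identically. For
  non-default group sizes counts scale proportionally.
* **Cortisol** — each subject's target log-AUC is drawn from the
  per-group normal (mean/SD as configured); a smooth
  anticipatory-rise/decay log-profile plus shape noise is then leveled so
  its trapezoid AUC *exactly* equals the target. Group calibration is
  therefore exact by construction. Sampling minutes default to
  0, 10, 35, 55, 75, 100 (the exact grid of the emulated protocol is not
  published; it is configurable). One subject (configurable) receives an
  incomplete profile.
* **Images** — GM/WM maps are constant tissue baselines (0.35/0.30)
  inside a brain slab, with multiplicative group effects on atlas
  regions, plus voxel noise (SD 0.05), smoothed with an 8-mm FWHM
  Gaussian kernel at 3-mm voxels to mimic the spatial correlation of
  VBM-style preprocessed output. The default effect table raises frontal
  and cingulate GM by 10% in GAD and lowers it by 10% in MD — opposite
  directions, so GM is informative for disorder-classification but weak
  for case-classification — and leaves WM untouched. The synthetic atlas
  is 30 axis-aligned boxes named after the 15 bilateral regions of the
  a-priori ROI set (basal ganglia, amygdala, hippocampus, thalamus,
  anterior cingulate, and frontal/orbitofrontal gyri), plus a WM slab; a
  real labeled atlas NIfTI is accepted as a drop-in at load time.

What the generator does **not** emulate: MRI physics, registration and
segmentation error, cortical topology, realistic cortisol circadian
dynamics, correlated questionnaire items, site effects. Passing tests on
synthetic cohorts therefore demonstrate that the *analysis machinery* is
correct and calibrated — not that any accuracy level is attainable on
real patients.

## Feature extraction

A voxel enters the analysis only if every subject provides data there
(value above a threshold, default 0.01, in all images) — the intersection
mask. Gray matter is additionally restricted to the 30 labeled ROIs
(`gm_rois`), white matter to the WM compartment (`wm_all`); `whole_brain`
lifts the ROI restriction. Intersection and ROI masking commute, so the
order is immaterial. Every imaging feature column records its voxel index
and region label; the provenance is checked exhaustively in tests.

## Cohort statistics

The ANOVA accepts either raw per-group vectors or printed n/mean/SD
summaries; the two paths agree to machine precision whenever the raw data
realize the summaries (SDs with ddof = 1). χ² is Pearson's without Yates
correction — the reference table's printed sex (1.653), handedness
(0.875) and smoking (1.262) statistics reproduce exactly under this
convention and not with the correction. Post hoc comparisons default to
Tukey's HSD (Games-Howell available for unequal variances). One printed
reference value, the education χ² (3.551 with df 2 but p .470), is
internally inconsistent and cannot be reproduced from its own counts
(Pearson gives 2.152); it is excluded from validation.

## Problem sizes in the test and acceptance runs

The default test suite and acceptance script are sized for a single CPU:
property tests use cohorts of 16–29 subjects on reduced grids (e.g.
20×24×20 at the default 3-mm voxels), 199-permutation tests, 20-seed
replicate sets, and 100 null cohorts for the type-I-error check; the
acceptance script runs the full 57-subject default cohort on the full
40×48×40 grid with 199 (single-modality) and 1000 (ensemble)
permutations. All of these are choices of scale, not of method: every
routine accepts the full-size settings (e.g. 5000 permutations)
unchanged.

## Known limitations

* The disorder-classification problem treats comorbid GAD+MD as GAD, per
  the emulated design; no three-class machinery is provided.
* Modality fusion requires complete data; there is no imputation.
* The generator's effect table is multiplicative and box-localized;
  diffuse or shape-dependent effects are out of scope.
* The ensemble permutation scheme's strict counting can return p = 0
  (see above); the add-one single-modality estimator cannot.
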