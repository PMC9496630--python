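# Methods

This document records the statistical model behind `emlscreen`, the default
parameters and why they were chosen, numerical conventions and tie-breaking
rules, and the package's limitations.

## 1. Data model

Input is a peak table: samples × metabolite features of GC-MS peak areas, a
per-sample internal-standard (IS) area, a binary class label (`CTRL` / `EC`),
and optionally a batch assignment. Missing cells represent peaks not detected
in a sample.

## 2. Batch quality control (`qc_filter`)

A batch passes when four conditions hold:

1. **Blank** — no peak above the detection floor (default 0).
2. **Standard mix** — every analyte of the standard mixture within 10%
   relative deviation of its expected IS-normalized area.
3. **Duplicate injection** — mean relative deviation over the 100
   largest-area peaks of a duplicated sample < 15%. The mean over the top-100
   is the aggregate; the per-peak maximum is also reported for inspection.
4. **Pooled sample** — the pooled QC injection's deviation from the running
   centroid of all prior batches' pooled injections, measured as
   ‖pooled − centroid‖ / ‖per-feature SD vector of prior pooled samples‖,
   is < 5%. The first batch has no history and passes this condition
   trivially; an explicit reference can be supplied instead.

The "within 5%" and "reproducibility" conditions are stated qualitatively in
the screening literature; the formulas above are this package's explicit
operationalizations, chosen to be scale-free and monotone in the obvious
failure modes (each synthetic corruption mode in `corrupt_batch` violates
exactly one condition).

After QC, features present in fewer than 80% of samples (threshold inclusive:
exactly 80% presence is kept) are removed before imputation.

## 3. Preprocessing (`preprocess`)

Fixed transform order: **IS-normalize → natural log → autoscale**.

- IS normalization divides every area by the sample's IS area; fold-change
  statistics are invariant to a common rescaling of all areas (tested).
- Missing cells are imputed before the log: `half_min` (half of the feature's
  minimum observed value, a detection-limit surrogate; default) or
  `feature_median`.
- The natural log is used; the base is irrelevant to any downstream
  quantity (autoscaling divides it out; fold changes exponentiate a
  difference of means in the same base).
- Autoscaling mean-centers each feature and divides by the sample (n−1)
  standard deviation. Parameters are fitted on a designated training subset
  only and frozen, so evaluation samples never leak into the transform.
  Features constant on the fitting subset are dropped with a warning; the
  constancy test uses `sd ≤ 1e-12 · max(1, |mean|)` because the floating-point
  SD of a constant log column is ~1e-16, not 0.

## 4. Feature screening (`feature_screen`)

Each feature receives at most one exclusion tag, evaluated in this fixed
order against the class indicator:

1. `correlation_high` — |Pearson r| ≥ 0.95 (near-duplicate of the label;
   suspect leakage or redundancy);
2. `correlation_null` — |r| ≤ 0.05 (carries no class signal);
3. `unstable` — strictly more than 80% of samples share one identical value;
4. `missing` — any remaining NaN.

A feature whose correlation is undefined (zero variance ⇒ NaN r) falls
through to the stability check, which necessarily catches it. The tagger is
idempotent: re-screening the retained set excludes nothing.

The optional genetic-algorithm wrapper (`ga_select`) searches binary feature
masks with tournament selection (size 2), uniform crossover (rate 0.8),
bit-flip mutation (rate 0.02), and elitism (2), using the cross-validated
accuracy of a chosen model kind as fitness. Defaults (population 50,
40 generations, 5-fold CV) are conventional GA settings, all configurable;
elitism makes the best-fitness trace non-decreasing (tested).

## 5. Base classifiers (`classifiers`)

Seven kinds, all scikit-learn estimators behind a uniform interface:

| kind | estimator | default grid |
|---|---|---|
| NB | GaussianNB | var_smoothing |
| GLM | LogisticRegression (L2) | C |
| FLM | LinearSVC + Platt calibration | C |
| DL | MLPClassifier (lbfgs) | hidden sizes, alpha |
| DT | DecisionTreeClassifier | depth, min leaf |
| RF | RandomForestClassifier (500 trees) | max_features |
| PLSDA | PLSRegression + nearest centroid | n_components |

Training is an exhaustive grid search under stratified k-fold CV (default
k = 10); the winner is the first grid point attaining the best CV accuracy
(first-wins tie-break, so results are order-deterministic), refitted on all
training data. Reported per model: CV accuracy, CV AUC, train accuracy, and
the overfit gap (train − CV accuracy).

**Admission gates** (all strict inequalities): CV accuracy > 0.65, CV AUC
> 0.85, overfit gap < 0.15. Strictness means a model exactly at a gate is
rejected.

**Confidence contract.** For probabilistic models, confidence =
2·|p(EC) − 0.5|. PLS-DA's decision function is the relative centroid margin
(d_CTRL − d_EC)/(d_CTRL + d_EC) ∈ [−1, 1]; defining predict_proba =
(1 ± decision)/2 makes the probabilistic formula reproduce the margin
exactly, so one contract covers every kind. Confidence is 0 at the decision
boundary, where the label defaults to `CTRL` (a non-positive score never
screens positive).

## 6. Ensemble score and threshold (`eml`)

Vote of model *m* on sample *x*:
`sign · 100 · cv_accuracy · confidence`, sign +1 for EC, −1 for CTRL. The
EML score is the plain sum over admitted models, bounded by ±100·n_models,
antisymmetric under flipping every vote, and exactly 0 for a balanced
equal-weight configuration.

The decision threshold maximizes the Youden index J = S + Sp − 1 over
candidate cuts at the midpoints of sorted unique scores plus ±∞; ties are
broken toward higher specificity, then the higher cut (a screening test
should prefer fewer false positives at equal J). The implementation matches a
brute-force oracle with the identical tie-break tuple on randomized tied
instances.

AUC and its variance come from DeLong's method via midrank structural
components; the AUC equals Mann–Whitney U/(n₁n₀) identically (tested). The
95% CI is computed on the logit scale, falling back to a clipped linear CI
when AUC ∈ {0, 1}.

The diagnostic panel reports TP/FP/TN/FN, S, Sp, PLR = S/(1−Sp),
NLR = (1−S)/Sp, PPV, NPV, and accuracy; any zero-denominator ratio is `None`,
rendered "ND".

## 7. Reporting (`report`)

- **Volcano:** fold change is the geometric-mean ratio EC/CTRL (difference of
  log means, exponentiated); p-values are Welch t-tests on the logs (Student
  optional). A feature is significant when FC > 2 or FC < 0.5 (strict) and
  p < 0.05; Benjamini–Hochberg q-values are also emitted but do not gate the
  flag (raw-p gating is the field convention this package follows).
- **PLS-DA diagnostics:** the latent-variable count is chosen by maximum CV
  accuracy (smallest count on ties); VIP uses the SSY-weighted formula whose
  mean squared value over features is identically 1 (validated to 1e-6); R²
  is in-sample, Q² is k-fold cross-validated 1 − PRESS/TSS, so Q² ≤ R²; the
  permutation test refits under label permutations and reports
  p = (1 + #{permuted Q² ≥ observed}) / (1 + n_perm), default n_perm = 2000.
  With the LV count fixed, the null distribution of p is uniform on its grid
  (verified by KS test in the acceptance suite).
- Plot helpers (volcano, score distribution, ROC) import matplotlib lazily
  with the Agg backend; the core package has no plotting dependency.

## 8. Synthetic cohorts (`synthetic_data`)

Peak areas are log-normal (base log-mean 11, log-sd 0.5) over 251 features by
default. Twelve default effect metabolites are planted: glycerol,
3-hydroxybutyric acid, and stearic acid raised at fold change 3; glycine,
phenyl pyruvic acid, serine, valine, urea, oxyproline, phenylalanine,
glyceraldehyde 3-phosphate, and gluconic acid lowered at fold change 1/3.
Missingness is MCAR at rate 0.02; the IS area is 1e6 ± 5%. Batch generation
emits runs of 25 injections with blank, standard-mix (15 molecules),
duplicate, and pooled QC injections; `corrupt_batch` produces batches that
fail exactly one QC condition by construction.

What the generator does **not** emulate: chromatographic drift within a
batch, correlated metabolite modules, retention-time misalignment,
missingness that depends on abundance (MNAR), class-dependent IS recovery,
or any real biological covariance structure. Conclusions about absolute
classifier performance on synthetic cohorts therefore do not transfer to
real sera; the generator exists to verify the machinery, not to simulate
biology. `qc_noise` defaults to 0.005 so that clean batches sit well inside
the pooled-QC 5% tolerance (observed deviations 0.007–0.017 across seeds)
while every corruption mode still fails deterministically.

## 9. Problem sizes and runtime

All defaults were exercised at: 200 samples/arm × 251 features, 10-fold CV,
all seven model kinds — about 21 s for the full pipeline on one CPU. Null
calibration uses 20 runs at 60 samples × 30 features with 5-fold CV; the
permutation-uniformity check uses 40 seeds at n_perm = 49 with the LV count
fixed at 1 (selecting the LV count on the observed labels would bias the
observed Q² upward relative to permutations and invalidate uniformity). The
complete test suite runs in about 4 minutes.

## 10. Limitations

- Two classes only; no multi-class or survival endpoints.
- The Youden threshold is chosen on a single evaluation split, not nested CV;
  reported panel metrics on that split are optimistically biased for small
  cohorts.
- DeLong CIs assume independent samples; repeated measures are not handled.
- The GA wrapper's fitness is CV accuracy of a single model kind; it does not
  guard against selection overfitting beyond the CV itself.
- The QC pooled-sample criterion needs at least one prior batch (or an
  explicit reference) to be informative.
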