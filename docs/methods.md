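# Methods

## The problem

Screening programmes accumulate short longitudinal series of routine
measurements per person. For people with metabolic syndrome, progression of
chronic kidney disease from stage 3a (eGFR 45–59 mL/min/1.73 m²) to 3b
(30–44) is clinically pivotal and rare, so the usable cohorts are small and
severely imbalanced. The question the scheme answers is not only *whether*
a model can predict progression, but *which* longitudinal summaries of
which measurements carry the signal — robustly, rather than according to
the idiosyncrasies of one learner.

## The scheme

1. **Cohort construction.** From a raw record table (one row per subject
   per examination, 19 continuous measurements plus eGFR), subjects with
   fewer than 3 or more than 12 examinations are dropped, as is any
   subject with a single eGFR reading below 15 (dialysis range; strict
   inequality). The staging window is the subject's **last three exams**:
   the two earlier exams must both be normal-range (eGFR ≥ 60, the "two
   consecutive ≥ 60" requirement) and the final exam's eGFR band assigns
   the group — experimental/progression for [45, 60), control for
   [30, 45), "others" (excluded) otherwise. Bands are half-open and
   configurable. The outcome is Y = 1 for the experimental group.

2. **Extended variables.** Each measurement's two predictor exams
   (v₁, v₂) are summarised four ways: closest C = v₂, mean
   M = (v₁+v₂)/2, sample standard deviation S (which for two points
   equals |v₂−v₁|/√2), and difference D = v₂−v₁ — 76 predictors from 19
   measurements. No imputation: a missing value is an error. Constant
   columns are passed through but flagged, because they would break
   min–max importance scaling downstream.

3. **Model zoo under nested CV.** Six importance-scoring classifiers
   (random forest, extra-trees, gradient-boosted trees, XGBoost,
   LightGBM, and L1-penalised logistic regression on standardised inputs)
   plus an unpenalised logistic benchmark are run through stratified
   10-fold nested cross-validation. Inner loops (9-fold over the outer
   training portion) pick hyperparameters by mean validation AUC; a
   singleton grid skips the inner loop. Training partitions — and only
   training partitions — are oversampled to class parity by random
   duplication (a minimal SMOTE is available). Each outer fold yields a
   metrics row (BA, SEN, SPE at threshold 0.5; AUC threshold-free) and a
   raw importance vector (impurity decrease for the forests and GBDT,
   split gain for XGBoost/LightGBM, |coefficient| for the penalised
   logistic model).

4. **Dual-scale importance.** Per model, raw fold vectors are averaged
   (arithmetic mean over folds), min–max rescaled to the **RIV** (0–100;
   best = 100), and ranked descending to the **ORV** (1 = best). Ties take
   the *worst* position of their block, so a run of zero-importance
   variables at the bottom all carry rank 76. Averaging before rescaling
   is the default (it keeps ORVs integral); rescaling per fold before
   averaging is available as `merge_order="scale_then_merge"`.

5. **Variable ensemble rules.** Per variable, the six per-model values are
   aggregated: RIV with arithmetic mean (AMA), geometric mean (GMA,
   zero-absorbing) and maximum (MA); ORV with AMA, median (RMA) and the
   modal rank (BCA). BCA returns the most frequent rank; if all six ranks
   are distinct it falls back to the worst rank, and a tie between equally
   frequent modes is also resolved to the worst — the "worst-case"
   convention, applied consistently.

6. **Union selection and refits.** For each scale, the union of the top-k
   variables over its three aggregates (k ∈ {4, 6, 8, 10, 12}) forms a
   candidate set; an aggregated-value tie straddling position k keeps the
   whole tied block (a conservative superset). The selector model
   (default: the L1 logistic learner, the strongest member here) is refit
   on every candidate set under the *same* outer folds as the
   all-76-variable baseline, so condition comparisons are paired.

## Synthetic cohorts

The screening database that motivates this design is access-restricted, so
the package ships a generator rather than data. Its defaults are the study
conditions: 335 subjects, 3 exams each, 33 progressors (class ratio
≈ 0.0985).

* Exam-1 values are multivariate normal over the 19 measurements
  (exchangeable correlation, default 0) with conventional
  location/scale choices for a middle-aged screening population (e.g. BUN
  16 ± 4.5 mg/dL, Hb 14.2 ± 1.5 g/dL, SBP 130 ± 15 mmHg); later exams
  follow a random walk with step SD = 0.4 × the between-subject SD, so C,
  M, S and D all vary independently enough to be separately detectable.
  Draws below a small positive floor are truncated and logged.
* The outcome is a conditional-logistic draw: η is a linear combination
  of standardised planted extended statistics (configurable
  variable/statistic/log-odds slope triples); subject i progresses iff
  ηᵢ + Gᵢ (G standard logistic) is among the top n_pos scores, with n_pos
  fixed by deterministic rounding of the class ratio. Marginally
  P(Y=1|η) = sigmoid(η − t), so an ordinary logistic fit recovers planted
  slopes unbiasedly while small cohorts hit exact counts.
* eGFR is generated directly (no creatinine equation): normal-range
  values (75 ± 8, reflected at 60) before the staging exam, then a
  uniform draw in the group's band — progressors in [45, 60),
  controls in [30, 45).

What the generator does **not** emulate: irregular visit timing and
dropout, measurement skewness (r-GT and TG are strongly right-skewed in
real life), within-subject correlation between different measurements'
trajectories, and any real association structure among the 19 variables.
Passing the synthetic studies therefore demonstrates that the machinery
recovers structure it is pointed at under honest cross-validation — not
that the specific variables selected on real screening data are correct.

## Validation studies and problem sizes

* **Reference worked example** (`analysis/07`): the bundled six-model
  RIV/ORV profiles of 12 extended variables are re-aggregated and the
  bundled top-12 rankings re-unioned; 71/72 aggregate cells and 10/10
  selection sets agree with the published values. The one disagreeing
  cell (BMI(S), ORV-BCA) is inconsistent in the source table itself: its
  profile contains a repeated rank 64, and the same modal rule that
  produces every other published cell yields 64, not the printed 76.
* **Planted-effect recovery** (`analysis/08`): 20 cohorts at n = 1000
  with three planted effects of standardised log-odds 2.0 — BUN(S),
  Hb(S), RBC(M), echoing variability-of-kidney-function and anaemia
  signals. Checked: all three land in the RIV top-8 union in ≥ 90% of
  replicates, and the refit on the selection matches or beats the paired
  baseline AUC in ≥ 80%.
* **Null calibration**: 10 effect-free cohorts at n = 335; the
  cross-validated AUC averages within ±0.07 of 0.5.

Replicate studies use the `FAST_GRIDS` preset (one candidate per model,
lighter ensembles of 50–100 trees); a single cohort analysis uses
`DEFAULT_GRIDS`, with small searches over one capacity parameter per
model and C ∈ {0.05, 0.2, 1.0} for the L1 learner. Grids are configuration,
not code.

## Numerical and design choices

* **RIV on a constant importance vector is undefined** and raises — it
  signals a degenerate model (e.g. all coefficients shrunk to zero), which
  should be inspected, not silently rescaled.
* **Tie handling** is worst-of-block for ORV (`rankdata(…, method="max")`
  on the negated values) and best-of-block for aggregated rank positions
  (`method="min"`), which is what makes the straddling-block top-k cut a
  superset rather than an arbitrary truncation.
* **Threshold 0.5** is used for SEN/SPE. Bagged trees refit on
  duplicated-minority data can still centre their probabilities below 0.5
  for minority cases (visible as low SEN for the forests at n = 1000);
  model adequacy and condition comparisons are therefore judged by AUC.
* **Seeds** thread from one user seed through generator, fold splitter,
  oversampler and every estimator; two runs with the same seed are
  byte-identical in all numeric outputs.
* **Degenerate folds** (single-class test fold) are flagged, excluded
  from fold means, and never silently imputed.

## Known limitations

* The two-exam window makes S and |D| perfectly collinear (S = |D|/√2);
  both are kept for interpretability, as tree learners split on either
  interchangeably, but linear members see duplicated information.
* With six models the BCA mode is shallow (frequencies rarely exceed 2–3),
  so BCA is the noisiest aggregate — consistent with its role as one vote
  among three per scale.
* The generator's planted effects act on realised extended statistics; it
  cannot express effects that differ between the two predictor exams'
  levels (e.g. threshold effects), and its independence default overstates
  how separable real measurements are.
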