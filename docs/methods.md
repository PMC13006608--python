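# Methods

`traumaprog` re-implements, as a tested and reusable pipeline, a
prognosis analysis for severe-trauma admissions: free-text diagnoses are
converted to numeric scores, regional injury severities are combined into
composite scores, features are screened statistically and by tree-ensemble
importance, and prognostic models are fitted and benchmarked.  All stages
run against a synthetic cohort generator so the whole pipeline is testable
without patient data.

## Synthetic cohort

The generator emulates a three-class severe-trauma registry: 108 cured,
130 improved and 54 poor-prognosis patients by default (292 total), with
under 5% missingness.  The outcome class is assigned first; everything
else is sampled conditionally on it.

* **Continuous features.** Clinical and laboratory panels in this setting
  are skewed and are summarised as median (P25, P75), so each feature is
  drawn from a log-normal distribution parameterised to hit per-class
  median/IQR targets exactly in expectation: `mu = log(median)` and
  `sigma = asinh(IQR / (2 median)) / z75` with `z75 = 0.6745`.  The default
  target table (`data/cohort_features.json`) covers 31 continuous
  features (age, vitals, coagulation, liver/kidney panels, protein
  markers).  Two printed-table oddities in the source profile were
  regularised: one non-monotone quartile triple was re-sorted, and two
  ties between the median and a quartile were kept as-is since the fit
  uses only the median and IQR.
* **Count features.** Transfusion and rescue counts have majority-zero
  distributions that a quartile-matched log-normal cannot represent; they
  are Poisson with class-dependent rates ordered cure < improved < poor.
* **Categorical features.** Ten symptom/treatment/demographic variables
  with per-class level probabilities taken from group-level frequency
  tables.
* **AIS profiles.** Six regional Abbreviated Injury Scale scores (0–6)
  drawn as binomial(5, p) with region- and class-dependent p; head/neck
  and chest dominate, mirroring a largely-TBI cohort, and severity rises
  with worse outcome.  These marginals are stylised, not quartile-matched.
* **Diagnosis texts.** Primary and other diagnoses are assembled by
  sampling keywords from the packaged keyword library, with a
  multiplicative odds bump (default 3x, half of it for the improved
  class) on modules whose library weight is at least 4, plus 2–5 neutral
  filler words chosen so that no filler or juxtaposition forms a library
  keyword.  Match counts are therefore exactly recoverable downstream.
* **Missingness.** Strictly MCAR, per cell at the configured rate
  (default 3%, must stay below 5%).  No MAR/MNAR mechanism is modelled.

What passing tests on this generator do **not** show: the generator draws
features independently given the class, so it carries none of the
cross-feature correlation structure (e.g. coagulation panels moving
together) of real registries; conclusions about collinearity handling on
real data do not follow from these tests.

## Diagnostic text scoring

Texts are NFKC-normalised, lower-cased, punctuation-stripped and matched
by codepoint substring (so non-space-delimited scripts work).  Every
occurrence of every keyword counts, and distinct keywords count
independently even when they overlap — a deliberate simplification; there
is no stemming, negation handling or embedding.  The patient score is
`F_i = sum_j delta_j N_ij` over the seven modules of each library.

Module weights `delta` are constrained to [0, 5] and chosen to maximise
the population variance (divisor n) of the score series — a dispersion
objective: a score that separates patients more carries more usable
information.  Since `F` is linear in `delta`, the objective is the
quadratic form `delta' C delta` with `C` the population covariance of the
count matrix, which both the GA and the exact grid solver exploit.

* **Integer encoding is the default** (weights in {0..5}): reported weight
  tables in this setting are integer-valued, and the full 6^7 grid
  (279,936 candidates) is enumerable as an exact reference.  A continuous
  encoding is available by configuration.
* **GA defaults**: population 60, 100 generations, tournament size 3,
  uniform crossover at 0.8, per-gene mutation 0.1, elitism 2.  The best
  objective per generation is recorded as a convergence curve.
* **Ties** between equal-objective weight vectors resolve to the
  lexicographically smallest vector, for deterministic reporting.
* A known wrinkle: the objective is a convex quadratic, so its box
  maximum always lies at a vertex of [0,5]^J, yet published weight tables
  of this kind report interior values (1–4).  Interior optima can only
  arise under additional constraints or early stopping; the solver here
  reports the true box optimum and the discrepancy is documented rather
  than resolved.
* An all-constant count matrix makes the objective identically zero; the
  solver returns a flagged degenerate result instead of an arbitrary
  vector.

## Composite AIS scoring

Six regions are used throughout: head/neck, face, chest, limbs+pelvis,
abdomen+pelvis, body surface.

* **CRITIC**: columns are min-max normalised (no direction flip — all AIS
  columns are severity-increasing); variability `S_j` is the sample
  (ddof=1) standard deviation of the normalised column; conflict
  `R_j = sum_k (1 - r_jk)` over Pearson correlations, with the self term
  contributing exactly 0 so the inclusive sum is used; information
  `C_j = S_j R_j`; weights are `C_j / sum C`.  A constant column gets
  `S_j = 0`, weight 0, and is flagged; correlations against it are taken
  as 0.  The divisor choice (n vs n-1) cancels in the normalised weights.
* **Equal weight**: the mean of the six regional scores (1/6 ≈ 0.167
  each).
* **ISS**: sum of squares of the three highest regional scores, and 75
  whenever any region scores 6 (the standard unsurvivable-injury
  convention).
* **Scheme comparison**: each composite is scored against the binary
  outcome by ROC AUC; for calibration the composite is first passed
  through a univariate logistic recalibration (raw composites are not
  probabilities), then a Hosmer–Lemeshow test with g = 10 risk-decile
  bins against chi-square with g − 2 df; decision-curve net benefit
  `NB(pt) = TP/n − (FP/n) pt/(1−pt)` is evaluated on a 0.01–0.99 grid
  with treat-all and treat-none references.
* **RTS / TRISS** baselines use the standard published coefficient sets,
  held as configuration data (RTS: 0.9368/0.7326/0.2908 on the coded
  GCS/SBP/RR; TRISS blunt: −0.4499 + 0.8085·RTS − 0.0835·ISS −
  1.7430·age-index).

## Imputation and univariate screening

Four imputation candidates — mean, mode, median, and chained-equations
multiple imputation (m = 5 posterior draws, aggregated by mean for
numeric and mode for categorical columns) — are all applied, and the one
distorting the observed data least is selected.  The distortion score is
the mean over affected numeric columns of
`|mean shift|/sd + |sd shift|/sd` relative to complete cases, with ties
broken in the fixed order mode, mean, median, multiple.

A consequence worth stating: filling at the observed mean keeps the
column mean exact and produces the smallest possible post-imputation
variance shrink, so among the three single-value fills the mean fill is
weakly optimal under this score on any numeric column; the multiple
imputation candidate (which restores spread through posterior draws) is
the only one that can beat it, and the mode wins ties.  The audit is
therefore most informative on discrete or mixed-type tables.

Univariate screening uses a per-group Shapiro–Wilk gate at 0.05: one-way
ANOVA when all three groups look normal, otherwise Kruskal–Wallis with
the standard tie correction; categorical features use the chi-square test
on the contingency table.  Zero-variance features are flagged, not
tested.  No multiple-testing correction is applied at this stage — the
screen is deliberately permissive, and downstream importance screening
does the pruning.  A timeliness filter removes named features (by default
rescue counts and surgery status, which are not reliably known at
admission) from the significant set.

## Rebalancing and feature screening

The binary task (good = cure+improved vs poor) is imbalanced about
4.4:1, so SMOTE (k = 5 minority neighbours, synthetic points uniform on
segments between minority neighbour pairs) is followed by edited nearest
neighbours (k = 3 majority vote) which deletes ambiguous rows but never
edits values.  Both are implemented on scikit-learn nearest-neighbour
queries.

Importance screening fits a 200-tree random forest (impurity importances)
and an XGBoost booster (gain importances), normalises each vector to sum
to one, and retains features at or above 5%.  The forest set D1 and
boosting set D2 are combined by union and intersection, and the four
candidate sets are compared with LightGBM under a stratified 8:2 split
with 5-fold CV on the training part, the best set flagged by test AUC.
An events-per-variable guard warns whenever retained features × 10
exceeds the positive-event count.

Attribution summaries use the boosters' built-in TreeSHAP (per-sample
additive attributions).  Each feature's direction label comes from the
sign of the correlation between its values and its attributions (what one
reads off a beeswarm plot); the mean signed attribution of a roughly
centred feature is near zero and is reported but not used for labelling.
Models without a TreeSHAP backend are rejected with an explanatory error.

## Stepwise logistic model and nomogram

Backward elimination starts from the full model and repeatedly removes
the predictor with the largest likelihood-ratio p-value while that value
exceeds `alpha_exit = 0.10`, breaking near-ties by the lower AIC of the
reduced model.  The final table reports B, SE, Wald = (B/SE)², the Wald
p-value, Exp(B) = e^B and the 95% CI `e^{B ± 1.96 SE}`.  Wald statistics
are recomputed from full-precision B and SE, so they need not match a
table recomputed from rounded figures.  Suspected perfect separation
(non-convergence or exploding estimates) sets a flag; a penalised fit is
the recommended fallback.

Note the statistics of this procedure: each truly-null predictor
independently survives with probability ≈ alpha_exit, so with ten null
candidates roughly `1 − 0.9^10 ≈ 65%` of runs retain at least one.  That
is a property of backward selection at 0.10, not an implementation
artefact.

The nomogram maps each retained predictor to a point scale proportional
to |B| × observed range, normalised so the largest contribution spans
0–100 points; the total-points-to-probability map inverts the linear
predictor through the logistic link and is monotone by construction.
Discrimination is the concordance index (ROC AUC for a binary outcome)
with a stratified-bootstrap CI; calibration is the bootstrap-refit decile
curve (default 1,000 replicates in the API; the pipeline demo uses 200)
summarised by mean absolute error between average predicted and observed
rates.

## Benchmark harness

All models are evaluated on identical stratified 5-fold outer splits
(each fold is an 80/20 split).  Rebalancing, standardisation and
hyperparameter tuning happen strictly inside each outer training fold;
per-fold test-index hashes are recorded in the report so fold hygiene can
be audited.  The zoo covers L1/L2 logistic regression, an RBF SVM
(C = 1.0, gamma = 0.1, balanced class weights), random forest, XGBoost
(max_depth 6, min_child_weight 3, learning rate 0.05, 200 trees,
gamma 0.1, subsample 0.8) and LightGBM.  The inner tuner is a small
genetic search over learning rate (log-uniform 0.01–0.3), depth (3–8)
and tree count (100–400), seeded at the fixed values above; a "fixed"
tuner that just uses those values is available and is what the
fast demo configuration uses.  Deep tabular attention models
(TabTransformer hybrids) are registered names without an installed
backend: requesting them logs a skip and never fails silently.

Metrics: ACC, PRE, TPR, TNR, F1 and AUC; macro-averaged one-vs-rest for
the three-class task in tables, micro-averaged for multiclass ROC
curves.  A class with no predicted positives reports precision 0 with an
explicit flag.  AUC confidence intervals are stratified-bootstrap
percentile intervals (1,000 replicates by default; smaller in the fast
configurations).  The overfit-gap report flags any model whose train
minus test AUC exceeds 0.15, the conventional prompt to add early
stopping or stronger L2.

## Pipeline and reproducibility

`trauma-pipeline run` executes simulate → score-text → composite →
screen → select → model → report from one YAML config.  The global seed
fans out as `stage_seed = (seed · 1009 + stage index) mod 2^31`, so each
stage is independently reproducible.  The manifest records a config hash
(excluding the output directory), per-stage output SHA-256 prefixes,
seeds and wall-clock; identical configs reproduce identical output
hashes, which the test suite asserts end-to-end.

## Problem sizes used by the shipped checks

The packaged test suite and `scripts/acceptance.py` choose sizes that
keep a laptop-class single-CPU run comfortable while preserving each
property being demonstrated: GA-vs-grid equivalence on 50 (tests) / 20
(script) seeded 40×7 count matrices against the full 6^7 grid; stepwise
parameter recovery at n = 2,000 with 5 signal and 10 noise predictors
over 50 seeds; univariate type-I calibration over 2,000 (tests) / 500
(script) null replicates at the 108/130/54 group sizes; and the full
pipeline on the 292-patient demo cohort with the fixed-value tuner, 2–4
benchmark models and 50–200 bootstrap replicates.

## Known limitations

* Text matching is exact substring matching; negated or historical
  mentions ("no evidence of fracture") count as matches.
* The synthetic cohort has no cross-feature correlations and no MAR/MNAR
  missingness, so imputation-method rankings on it are not evidence about
  real registries.
* The CRITIC weights of a cohort depend on its AIS marginals; weights
  computed on synthetic data will not match any published weight table.
* Backward selection at alpha_exit = 0.10 retains stray null predictors
  by design (see above); use a stricter exit threshold or penalised
  regression when false inclusions are costly.
* TRISS/RTS coefficients are the classic published sets; they are
  baselines, not re-calibrated models.
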