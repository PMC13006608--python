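# traumaprog

Prognosis modelling for severe-trauma cohorts: diagnostic free-text
scoring, composite injury-severity weighting, statistical and
importance-based feature screening, and prognostic model benchmarking —
packaged as a tested, seed-reproducible pipeline with a synthetic cohort
generator so every stage runs without patient data.

## Who this is for

Clinical data scientists and biostatisticians building prognostic models
for trauma registries, where admissions carry free-text diagnoses,
per-region Abbreviated Injury Scale (AIS) scores, lab/vital panels and a
three-class outcome (cure / improvement / poor prognosis), and where the
poor-prognosis class is heavily outnumbered (about 4.4 : 1 after
dichotomisation).

## What it computes

**Diagnostic text scores.** Each diagnosis text is matched against a
seven-module keyword library, giving counts `N_ij`; the patient score is

    F_i = Σ_j δ_j · N_ij ,    δ_j ∈ [0, 5]

with module weights δ chosen to maximise the population variance
`σ² = (1/n) Σ_i (F_i − F̄)²` of the score series (more dispersion, more
discriminative information).  A genetic algorithm searches the integer
box; an exhaustive 6⁷-grid solver provides the exact reference.

**Composite AIS severity.** Three parallel schemes over six body
regions: CRITIC objective weights (variability `S_j` = std of the
min-max-normalised column, conflict `R_j = Σ_k (1 − r_jk)`, information
`C_j = S_j·R_j`, weights `C_j / Σ C`), the equal-weight mean, and the
Injury Severity Score (sum of squares of the three highest regional AIS,
75 if any region scores 6) — compared by AUC, Hosmer–Lemeshow
calibration and decision-curve net benefit, with RTS/TRISS as classical
baselines.

**Screening and modelling.** Simulated-imputation selection over
mean/mode/median/multiple candidates; three-group univariate tests with
a normality gate; SMOTE-ENN rebalancing; random-forest and XGBoost
importance screening at a 5% share threshold with union/intersection
candidate sets evaluated by LightGBM; TreeSHAP direction summaries;
backward stepwise logistic regression (LR exit at 0.10, AIC tie-break)
with odds ratios `Exp(B) = e^B`, a 0–100-point nomogram, bootstrap
calibration and C-index; and a nested-CV benchmark of penalised
logistic, SVM, random forest and boosted-tree models with a GA
hyperparameter tuner.

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.

## Worked example

```python
import numpy as np
from traumaprog import synthetic_cohort as sc, text_scoring as ts, injury_composite as ic

spec = sc.CohortSpec(seed=7)                 # 108 cured / 130 improved / 54 poor
records = sc.generate_cohort(spec)
df = sc.cohort_to_frame(records)
y = sc.dichotomize_outcome(records)
print(len(records), int((y == 0).sum()), int(y.sum()))
# 292 238 54    -> good vs poor prognosis after merging cure+improved

lib = ts.default_libraries()["primary"]
counts = ts.count_matrix(df["primary_dx_text"], lib)
sol = ts.optimize_weights(counts, ts.GAConfig(seed=7))
print(round(sol.objective, 3))
# 42.657        -> maximised variance of the primary diagnostic score

ais = df[[f"ais_{r}" for r in ic.REGIONS]].to_numpy(float)
print(ic.critic_weights(ais).to_frame().round(3))
#                 variability  conflict  information  weight
# head_neck             0.227     4.444        1.008   0.159
# face                  0.216     4.838        1.044   0.164
# chest                 0.251     4.715        1.185   0.187
# limbs_pelvis          0.242     4.588        1.112   0.175
# abdomen_pelvis        0.230     4.921        1.133   0.179
# body_surface          0.177     4.881        0.865   0.136

print(ic.iss_score(np.array([5, 4, 3, 2, 1, 1])))
# 50            -> 25 + 16 + 9, the three highest regional AIS squared
```

The CRITIC table satisfies `information = variability × conflict` exactly
and its weights sum to one; on synthetic data the weights reflect the
generator's AIS marginals, not any published cohort's.

The full pipeline (simulate → score text → composite → screen → select →
model → report) runs from one config:

```bash
trauma-pipeline run --seed 17 --out run_out/
```

writing `scored.csv`, `univariate_report.csv`, `screening_report.json`,
`stepwise_table.csv`, `nomogram.json`, `benchmark_report.json` and a
`manifest.json` whose per-stage output hashes are identical across runs
with the same seed.

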