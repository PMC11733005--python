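# tinnidyn

Feature-based analysis of daily tinnitus diaries: does the *shape* of a
patient's day-to-day symptom trajectories carry their treatment response?

Patients in tinnitus trials can rate ten questions (tinnitus distress,
loudness, tinnitus-related thoughts, happiness, jaw and neck tension,
movement, stress) every evening on a 0–100 visual analogue scale over a
12-week treatment phase — up to 84 entries, submitted all-or-none per day.
`tinnidyn` turns each of the ten per-question series into ten time-series
features (median crossings, flat spots, spectral entropy, Hurst exponent,
lumpiness, stability, and the loess-trend strength/linearity/curvature plus
a Teräsvirta-type nonlinearity statistic), giving 100 named predictors per
patient, and models ordinal clinical improvement (CGI-I, 1 = very much
better … 7 = very much worse) with a reversed cumulative-logit elastic net:

    P(Y ≥ k | x) = logistic(θ_k + xᵀβ),   k = 2..7
    minimize  (1/n)·NLL + λ[α‖β‖₁ + (1−α)/2‖β‖₂²],   α = 0.5

so a positive log-odds coefficient means the feature rises with clinical
worsening. λ is tuned by 5-fold nested cross-validation over a 20-value
path from λ_max (the smallest penalty that zeroes every coefficient), with
per-fold AIC selection and held-out log-likelihood deciding the final λ;
model fit is the held-out McFadden pseudo-R². A sensitivity sweep repeats
the analysis at minimum-compliance thresholds from 50% to 90% of the 84
expected days. Because trial diary data is not publicly distributable, the
package ships a synthetic cohort generator with known ground truth
(planted linear trends, planted variance dynamics, Beta-distributed
compliance) so every stage is testable end to end.

Intended users: biostatisticians and EMA/diary-study methodologists who
want a reproducible, tested implementation of this analysis for their own
diary datasets or for simulation studies of its behaviour.

## Worked example

```python
import tinnidyn as td
from tinnidyn.pipeline import prepare_design
from tinnidyn.ordinal import nested_cv

# synthetic cohort: 300 patients, 84-day diaries, known planted signals
diaries, outcomes, truth = td.generate(td.SyntheticConfig(n_patients=300, seed=1))

# 50% minimum compliance + variability eligibility -> features + outcome
F, y, ids = prepare_design(diaries, outcomes, min_rate=0.50)
print(F.shape)                       # (281, 100)

res = nested_cv(F.to_numpy(), y, seed=1, feature_names=tuple(F.columns))
print(round(res.chosen_lambda, 4))   # 0.0167
print(round(res.test_mcfadden, 3))   # 0.925
print(res.final_fit.n_nonzero)       # 29
coef = dict(zip(F.columns, res.final_fit.beta))
for k in ("t-thoughts_linearity", "jawbone_linearity", "happiness_linearity"):
    print(k, round(coef[k], 2))
# t-thoughts_linearity 1.78      (thoughts decline with improvement)
# jawbone_linearity 1.71         (jaw tension declines with improvement)
# happiness_linearity -2.0       (happiness rises with improvement)
```

281 of 300 simulated patients complete at least 42 of 84 diary days and
pass the variability filter. The tuned model reaches a held-out McFadden
R² of 0.925 (mean over the five held-out folds) and selects 29 of the 100
features, among them the three planted linearity signals with their
generative signs: positive log odds for tinnitus-thoughts and jaw-tension
linearity (rising trends accompany worse outcomes) and negative for
happiness linearity.

The same analysis from the shell:

```bash
tinnidyn simulate --n 300 --seed 1 --out cohort/
tinnidyn validate --diary cohort/diary.csv --outcomes cohort/cgi.csv
tinnidyn features --diary cohort/diary.csv --out features.csv
tinnidyn fit --features features.csv --outcomes cohort/cgi.csv --seed 1 --out fit.json
tinnidyn run --config run.yaml      # full report incl. compliance sweep
```

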