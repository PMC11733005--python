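# Methods

`tinnidyn` implements a feature-based analysis of daily tinnitus diaries:
ten evening questions on a 0–100 visual analogue scale (VAS) over a
12-week (84-day) treatment phase are summarized per patient by ten
time-series features each, and the resulting 100 predictors are used to
model ordinal clinical improvement (CGI-I, seven categories) with a
penalized cumulative-logit regression. This note records the model, the
numerical choices, and what the synthetic cohort does and does not
emulate.

## Diary semantics

A diary day is *complete* when all ten questions have values; the app
design only accepts complete submissions, so completeness is the unit of
compliance: `compliance = |completed days| / 84`, with the denominator
fixed at 84 regardless of enrollment irregularities. Partial days (possible
in malformed or synthetic input) remain in the per-question series but
never count toward compliance. Compliance filters are inclusive at the
threshold (42/84 days passes the 50% filter), and filtered cohorts are
nested across thresholds — the property the sensitivity sweep relies on.

Patients are eligible for feature extraction only if every question shows
a strictly positive range over its observed days ("minimal variability").
This is the weakest eligibility rule under which each feature is either
well defined or degrades to a documented convention.

## Time-series features

Features operate on the observed values of one question in temporal order
with gaps closed: missing days are neither imputed nor encoded as spacing.
Equal spacing of observed points mirrors the behaviour of the standard
feature-extraction libraries this feature set comes from.

- **crossing-points** — number of sign changes of the indicator
  `x_i <= median(x)`.
- **flat-spots** — longest run of consecutive points inside one of ten
  equal-width bins spanning [min, max]; a zero-range series returns `n`.
- **entropy** — Shannon entropy of the normalized periodogram (demeaned
  series, the ⌊n/2⌋ positive Fourier frequencies, no taper) divided by
  `log ⌊n/2⌋`; 1 is white-noise-like, values near 0 indicate a dominant
  frequency or trend.
- **hurst** — 0.5 + d̂, clamped to [0, 1], where d̂ is the Whittle
  (frequency-domain maximum-likelihood) estimate of the fractional
  differencing order on [−0.5, 0.5]. A rescaled-range estimator is
  available via `hurst(x, method="rs")` for cross-checking.
- **lumpiness / stability** — sample variance (n−1 denominator) of the
  per-window variances / means over non-overlapping 10-point windows,
  trailing partial window discarded, series standardized to mean 0 / sd 1
  first (constant series → 0). Both need at least two complete windows
  (n ≥ 20); shorter series yield NaN sentinels.
- **trend / linearity / curvature** — from an additive trend + remainder
  decomposition (no seasonal term: daily data has no modelled sub-daily
  period). The trend is a loess smooth on the observation index: local
  quadratic regression with tricube weights over the ⌈0.75·n⌉ nearest
  neighbours (span and degree configurable; local-quadratic reproduces
  linear and quadratic series exactly). Trend strength is
  `1 − Var(remainder)/(Var(remainder)+Var(trend))`, clamped to [0, 1],
  with 0 returned when both variances vanish. Linearity and curvature are
  the degree-1 and degree-2 coefficients of an orthonormal polynomial
  regression of the trend on the index, oriented so rising trends have
  positive linearity and convex trends positive curvature; linearity is
  odd and curvature even under time reversal.
- **nonlinearity** — a Teräsvirta-style neural-network test with
  embedding dimension 1: regress `x_t` on `x_{t−1}`, then test the
  quadratic and cubic lag terms in an auxiliary regression; the statistic
  `n·(SSE0 − SSE1)/SSE0` is reported as `10·stat/n`. Degenerate
  regressions return 0 with a logged warning. Note that processes whose
  conditional mean is linear *in their own lag* (e.g. the square of an
  AR(1)) correctly show no signal here.

Per-feature length preconditions (n ≥ 2 for the counting features, ≥ 8 for
entropy, ≥ 10 for the trend block, ≥ 20 for hurst, nonlinearity and the
window features) produce NaN sentinels rather than errors inside
`extract_all`; the modelling stage refuses incomplete vectors. At the 50%
compliance operating point every question has ≥ 42 observations, so all
100 features are finite.

## Ordinal elastic net

The response is modelled with a reversed-direction cumulative
(proportional-odds) logit: `P(Y ≥ k | x) = logistic(θ_k + xᵀβ)` for
categories k = 2..C with non-increasing thresholds θ. Reversing the
cumulative direction makes a positive coefficient push mass toward higher
(clinically worse) categories, so regression signs agree with the
correlation screen. Only categories observed in the data are modelled.

The fit minimizes
`(1/n)·NLL + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)` with α fixed at 0.5 and the
thresholds unpenalized. The solver is accelerated proximal gradient
descent with backtracking: soft-thresholding yields exact zeros in β, and
thresholds stay ordered through the reparameterization
`θ_{k+1} = θ_k − exp(δ_k)`. Convergence requires the objective change to
drop below 1e-8 together with a max parameter change (on the natural θ/β
scale) below 1e-6, or a sustained stall of 25 consecutive sub-tolerance
objective changes. The stall rule, plus box constraints (|logit| ≤ 50,
log-gaps in [−15, 5]), handles boundary optima: when a training sample
has an empty response category its threshold diverges, and the gradient
vanishes exponentially faster than the iterates settle, so a pure
parameter-change criterion would never fire. Coefficients below 1e-12 in
magnitude after the final step are truncated to exact zero.

`λ_max` is the KKT bound `max_j |∂(mean NLL)/∂β_j| / α` evaluated at the
intercept-only solution (empirical cumulative logits); fitting at λ_max
returns β = 0 exactly and category probabilities equal to the empirical
frequencies. The path is 20 log-spaced values from λ_max down to
0.01·λ_max, warm-started.

### Nested cross-validation

Five seeded folds partition the sample; fold assignment shuffles within
each outcome category and deals round-robin, which stratifies frequent
categories and spreads rare ones as evenly as possible (a rare category
concentrated in one fold would otherwise vanish from that fold's training
portion). Per fold: columns are re-scaled on the training portion (the
scaling applied to the held-out fold — leakage-safe; `scale_within_folds=False`
reproduces the simpler scale-once behaviour), a fold-specific λ path is
built, all 20 fits are ranked by AIC with `df = #nonzero(β) + #thresholds`,
and the selected model is scored on the held-out fold. The λ whose fold
shows the best held-out per-observation log-likelihood is refit on all
data for the final coefficients. Model fit is the mean held-out McFadden
pseudo-R² (`1 − ll_model/ll_null`, null = intercept-only model fit on the
training fold and evaluated on the held-out fold); the mean is one of
several defensible aggregations and the per-fold values are always
reported alongside.

A known behaviour of AIC selection in the p ≈ n regime: with 100
predictors and ~120 training observations, the dense end of the path can
reach a near-saturated training likelihood whose gain exceeds the 2·df
penalty, so AIC can prefer heavily overfit models even on pure noise.
The held-out comparison across folds usually rescues the final λ, but
when every fold overfits, the final model is dense. This is a property of
the selection rule itself, visible in the null-behaviour suite, not a
solver artifact; the sweep surfaces it as small chosen λ with poor
held-out fit.

## Analysis pipeline

The correlation screen computes Spearman ρ (average-rank ties) between
each feature and CGI-I, reported as a 10×10 grid with rows and columns
ordered by mean coefficient; no p-values are computed and no multiplicity
correction applied — the screen is descriptive and the package refuses to
print significance for it. Relevance decomposes the fitted |log odds| into
per-question and per-feature sums; both margins conserve ‖β‖₁. The screen
and the penalized selection can disagree under collinearity; both are
reported without reconciliation.

The sensitivity sweep re-runs the tuned model at minimum-compliance rates
0.50–0.90 in 0.05 steps. Features are extracted once per patient (a
patient's observed series does not depend on the threshold); each rate
re-filters, re-scales within folds, and re-tunes λ with the same seed
policy. Subsamples under 30 patients are skipped with a warning.

## Synthetic cohort

The generator emulates the measurement design, not the trial: per patient
a latent standard-normal improvement score is thresholded at cutpoints
implied by the CGI-I category probabilities (default
.03/.17/.26/.39/.14/.01/0 — the zero keeps the worst category empty, as
observed); trajectories follow
`clip(μ_q + b_q·s·t + ε_t, 0, 100)` with severity score `s = CGI − 4`.
Default slopes (VAS points per day per severity unit) are +0.15 for
tinnitus thoughts and jaw tension, −0.15 for happiness (the headline
signals), +0.06 for the loudness and daily-distress questions, 0
elsewhere; noise is i.i.d. Gaussian with sd 8 (an optional AR(1) knob
exists and is off by default — day-to-day autocorrelation of real diaries
is unknown). For momentary loudness the noise sd evolves as
`8·exp(0.6·s·(t/83 − ½))`, shrinking over time for improvers — a planted
variance-dynamics (lumpiness) signal whose direction is configurable.
Whole days are dropped jointly with probability `1 − c_i`,
`c_i ~ Beta(6.05, 1.71)` (mean ≈ 0.78, sd ≈ 0.14), so generated data is
always all-or-none.

What passing tests show: the pipeline recovers planted monotone-trend and
variance-dynamics structure from ordinal outcomes at realistic sample
sizes, with correct signs, and stays near-empty on permuted labels (up to
the AIC caveat above). What they do not show: performance on real diaries,
whose autocorrelation, floor/ceiling behaviour, weekly rhythms, and
missingness mechanisms (here missing-completely-at-random given a
patient-level rate) are all richer than the generator.

## Problem sizes in the test suite

The simulation suites run the study conditions (n = 150 and n = 300
cohorts, p = 100) at 10–20 replicates; the quoted pass fractions scale
accordingly (e.g. ≥ 9/10 where a 90% rate is required). The end-to-end
report on the packaged 60-patient demo cohort runs in well under a minute
on one CPU.
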