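# Methods

This document describes the statistical model behind `yrbsprev`, the
synthetic-survey generator used for development and testing, the numerical
choices made in the implementation, and the package's known limitations.

## Problem

State-representative school-based health surveys (YRBS-style) ask about
sexual orientation in only a subset of participating states and years.  Two
binary outcomes are of interest for every respondent:

- **`lgb_identity`** — 1 if the respondent reports a gay, lesbian, or
  bisexual identity; heterosexual, "not sure", and missing responses code
  to 0.
- **`same_sex_contact`** — 1 if the reported sex of sexual contacts implies
  same-sex contact: female respondents reporting contact with females, male
  respondents reporting contact with males, or any respondent reporting
  contact with both sexes.  Missing contact responses code to 0; a missing
  sex response codes to 1 only under the "both sexes" rule.

The goal is to estimate, for every state, the survey-weighted proportion of
high-school students with each outcome — including states whose surveys never
asked the focal questions — by learning individual-level response patterns
from the states where the outcome *was* observed.

## Estimation pipeline

1. **Feature encoding.**  Every non-focal questionnaire item (plus the
   respondent's sex) becomes a block of one-hot level indicators with the
   lowest level as the reference, plus one missing-data indicator.  Missing
   responses are imputed to the training data's modal level; the modal map
   and the column registry are learned from training rows only and then
   applied unchanged to held-out rows, so a question never asked in a
   held-out state simply produces an all-ones missing indicator.
2. **Individual-level model.**  Eight interchangeable model families predict
   the probability of the outcome for each respondent: `ols`,
   `ridge_linear`, `lasso_linear` (linear probability models, predictions
   clipped to [0, 1]), `logistic`, `ridge_logistic`, `lasso_logistic`, and
   two tree ensembles, `random_forest` and `gbrt` (gradient-boosted trees).
   Hyperparameters are tuned by nested state-blocked cross-validation
   minimizing the Brier score, so tuning never sees the held-out state.
3. **State aggregation.**  Predicted probabilities are aggregated to a state
   proportion with the survey weights:
   `sum(w_i p_i) / sum(w_i)` over the state's target-year respondents.
4. **Evaluation: leave-one-state-out (LOO).**  Each state with an observed
   outcome is held out in turn; the model trains on all other
   outcome-observed states and predicts the held-out state's proportion.
   Agreement between predictions and observed weighted proportions is
   summarized by ICC(2,1) — two-way random-effects, absolute-agreement,
   single-rater intraclass correlation computed from the classical mean
   squares — which, unlike Pearson correlation, penalizes systematic bias
   and scale shrinkage.
5. **Prediction intervals.**  The LOO residuals (observed − predicted) of
   the *other* evaluated states form an empirical error distribution:
   location = mean residual, scale = SD (ddof = 1), df = n − 1.  A state's
   interval is `point + location ± t_{(1+level)/2, df} · scale`, clipped to
   [0, 1].  A state's own residual never enters its interval, and residual
   pools are task- and outcome-specific.
6. **Tasks.**  Three prediction tasks are distinguished: same-year
   prediction with the other focal outcome as a predictor (task 1),
   same-year prediction without it (task 2), and prediction of a state's
   target-year proportion from its most recent earlier survey (task 3).
   Final estimates prefer observed proportions, then task 1, 2, 3.

## Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `interval_level` | 0.95 | probability | conventional nominal coverage |
| `n_tune_folds` | 3 | folds (state-blocked) | smallest split giving stable Brier rankings with tens of states |
| `lambda` (ridge/lasso) | grid 10^{-2..2} | penalty | brackets the useful range for one-hot survey designs |
| `n_trees` | 200–800 | trees | ICC plateaus past a few hundred trees; larger only costs time |
| `max_depth` | 4–16 | levels | depth 4 suffices for pairwise interactions (gbrt); forests prefer deeper trees |
| `learning_rate` (gbrt) | 0.1 | shrinkage | standard small-step boosting |
| `max_features_per_split` | "sqrt" (rf), 1.0 (gbrt) | fraction/rule | sklearn defaults; "sqrt" keeps forests fast on wide one-hot designs |

## Synthetic survey generator

No public individual-level multi-state survey with these outcomes exists, so
the package ships a generator that emulates the *structure* of 2013–2017
state surveys and provides known ground truth.

**What it emulates**

- ~40 states, three survey waves with partial state participation, a
  79-item questionnaire (3 focal items + 76 other questions with 2–7
  response levels), uniform question-level omission (a state-year may not
  ask a question at all) and MCAR item missingness, log-normal survey
  weights normalized to mean 1 within each state-year.
- Identity prevalence: each state draws a climate score `u_s ~ N(0, 1)`;
  prevalence `p_s = expit(mu + sigma·u_s)` with `(mu, sigma)` solved
  numerically so that the prevalence distribution has mean 9,375 and SD
  1,228 per 100,000 — the scale of published state estimates.
- Contact prevalence: `c_s = q0 + p_s (q1 − q0)` with
  `P(contact | LGB) = q1 = 0.75` and `q0` solved so the mean is 7,079 per
  100,000.  Contact prevalence is below identity prevalence in every state,
  matching the consistently observed ordering.
- Covariate signal: respondents get a latent risk trait; informative
  question *pairs* are correlated Gaussians discretized into 4 levels, with
  within-pair correlation depending linearly on the state climate
  (`r_s = r0 + r1·u_s`).  The respondent's risk score is the mean of
  within-pair products of centered level scores, and the outcome logit is
  an affine function of it, with the per-cell intercept solved by Brent's
  method so the cell's mean probability equals `p_s` exactly.  This makes
  state differences *compositional* (joint response patterns) while every
  question's marginal distribution is identical across states — a signal
  additive/linear models cannot see but trees can, which is what makes the
  model-ranking experiments meaningful.  `signal_strength = 0` severs the
  covariate–outcome link entirely for negative controls.

**What it does not emulate**

- Real questionnaire content, skip patterns, or informative (non-MCAR)
  missingness.
- Clustered school/classroom sampling designs; weights are i.i.d.
  log-normal rather than the product of a design's stages.
- Demographic structure beyond a binary sex item; no age/grade/race fields.
- Year-over-year trends: a state's true prevalence is constant across
  waves.
- Measurement error or mode effects in the focal questions.

## Numerical choices

- Intercept calibration per state-year cell uses `scipy.optimize.brentq` on
  the mean-probability equation; the bracket is expanded geometrically until
  it straddles the root.
- Linear-model predictions are clipped to [0, 1] *after* fitting; the
  degenerate cases (single-class outcome, empty predictor set) return a
  constant model equal to the training mean.
- ICC(2,1) is computed from mean squares in double precision and truncated
  below at −1; its p-value is the F-test `sf(MSR/MSE, n−1, (n−1)(k−1))`.
- The residual-t interval treats states (not respondents) as the
  exchangeable unit, so df is the number of pooled residuals minus one.
- Feature matrices are `float32` one-hot blocks; models that need `float64`
  cast internally.
- All stochastic components (generator, fold assignment, forests) are
  driven by explicit integer seeds; identical seeds give byte-identical
  CSV serializations.

## Problem sizes

Development and test scales are package choices, made to keep the full test
suite within a desktop single-CPU budget: evaluation experiments use tens of
states with hundreds to thousands of respondents per state-year; the
parameter-recovery experiment uses 30 states × 2,000 respondents with the
clean strong-signal generator configuration (no item missingness or question
omission), which is the regime where the interaction signal is fully
learnable by boosted trees.

## Limitations

- ICC ≥ 0.8 recovery requires the clean strong-signal regime; with the
  default 10% question-omission rate a third of state-year cells lose at
  least one informative question and recovery degrades substantially — an
  honest reflection of how missing questionnaire blocks hurt small-area
  prediction.
- Tree predictions of state proportions are shrunk toward the grand mean
  (regression dilution at the individual level), so absolute-agreement ICC
  is achieved through high correlation despite mild scale shrinkage; no
  post-hoc recalibration of the spread is attempted.
- The residual-t interval assumes state exchangeability; with very few
  observed states (< ~8) the df is small and intervals are wide.
- Linear probability models can be poorly calibrated near 0; they are kept
  for comparability, not recommended for final estimates.
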