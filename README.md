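# yrbsprev

Small-area prediction of state-level sexual-minority prevalence from
YRBS-style survey microdata.

## The problem

State-representative school-based health surveys ask about sexual
orientation in only a subset of participating states and years.  Two binary
respondent-level outcomes are of interest:

- **LGB identity** — reporting a gay, lesbian, or bisexual identity;
- **same-sex sexual contact** — the reported sex of sexual contacts implies
  same-sex contact given the respondent's sex.

`yrbsprev` estimates the survey-weighted proportion of students with each
outcome in *every* state — including states whose questionnaires never asked
the focal questions — by (1) training individual-level probability models
(linear, logistic, penalized, random-forest, and gradient-boosted-tree
families) on the other questionnaire responses in states where the outcome
was observed, (2) aggregating predicted probabilities to survey-weighted
state proportions, (3) validating by leave-one-state-out cross-validation
scored with the absolute-agreement intraclass correlation ICC(2,1), and
(4) attaching prediction intervals from the Student-t fit to held-out state
residuals.  A calibrated synthetic-survey generator with known ground truth
supports development, testing, and power analysis.  See
[docs/methods.md](docs/methods.md) for the full model description.

## Test

```bash
python -m pytest -q tests/
```

The suite contains fast unit/property tests plus a slower acceptance module
(`tests/test_acceptance.py`) that runs the full pipeline on seeded synthetic
surveys; the whole run fits a single desktop CPU.

## Worked example

The snippet below simulates a single-wave survey in which one state (`S03`)
never asked the identity question, evaluates a logistic model by
leave-one-state-out cross-validation, and produces a final estimate (with a
residual-t interval) for the unobserved state.  It takes about a minute on
one CPU.

```python
from yrbsprev import (
    GeneratorConfig, ModelSpec, attach_outcomes, generate_synthetic_survey,
    icc, loo_state_cv, predict_unobserved_states,
)

# 1. Simulate a single-wave survey: 20 states, 2,000 respondents each, no
#    question omission; one state (S03) never asked the identity item.
config = GeneratorConfig(
    n_states=20,
    respondents_per_state=(2000, 2000),
    years=(2017,),
    year_probs=(1.0,),
    interaction_flag=False,      # main-effects covariate signal
    question_omission_rate=0.0,
    states_without_identity=("S03",),
    seed=7,
)
dataset, truth = generate_synthetic_survey(config)
outcomes = attach_outcomes(dataset)
print(f"{len(dataset.data)} respondents, {len(dataset.states)} states, years {dataset.years}")

# 2. Leave-one-state-out evaluation of a logistic model on the
#    same-year-without-other-outcome task.
spec = ModelSpec("logistic", seed=7)
result = loo_state_cv(dataset, outcomes, spec, "same_year_without_other", "lgb_identity")
frame = result.to_frame()
value, pval = icc(frame["point"], frame["observed"])
print(f"LOO ICC(2,1) = {value:.3f} (p = {pval:.4f}) over {len(frame)} states")
print(frame[["state_id", "point", "lower", "upper", "observed"]].round(4).to_string(index=False))

# 3. Final estimates: observed proportions where available, model predictions
#    (with residual-t intervals) for the state that never asked the question.
estimates = predict_unobserved_states(dataset, outcomes, spec, "lgb_identity")
pred = estimates[estimates["source"] == "predicted"]
print(pred[["state_id", "task", "point", "lower", "upper"]].round(4).to_string(index=False))
true_s03 = truth.set_index("state_id").loc["S03", "true_lgb_prevalence"]
print(f"S03 generator truth: {true_s03:.4f}")
```

Output:

```text
40000 respondents, 20 states, years (2017,)
LOO ICC(2,1) = 0.653 (p = 0.0011) over 19 states
state_id  point  lower  upper  observed
     S01 0.0942 0.0754 0.1112    0.0957
     S02 0.0930 0.0746 0.1103    0.0883
     S04 0.0769 0.0594 0.0939    0.0667
     S05 0.0787 0.0599 0.0957    0.0806
     S06 0.0906 0.0718 0.1069    0.0971
     S07 0.0858 0.0674 0.1031    0.0814
     S08 0.0953 0.0781 0.1122    0.0838
     S09 0.0903 0.0718 0.1061    0.0997
     S10 0.0903 0.0716 0.1065    0.0978
     S11 0.0933 0.0745 0.1101    0.0975
     S12 0.0981 0.0800 0.1132    0.1103
     S13 0.0866 0.0709 0.1025    0.0694
     S14 0.0903 0.0722 0.1075    0.0828
     S15 0.0820 0.0634 0.0993    0.0793
     S16 0.1012 0.0825 0.1177    0.1072
     S17 0.0909 0.0720 0.1078    0.0936
     S18 0.0833 0.0666 0.0999    0.0699
     S19 0.0865 0.0677 0.1036    0.0868
     S20 0.0898 0.0710 0.1064    0.0946
state_id                 task  point  lower  upper
     S03 same_year_with_other 0.0802 0.0712 0.0892
S03 generator truth: 0.0834
```

The held-out-state interval for `S03` brackets the generator's true
prevalence.

## Command-line interface

The same pipeline is available as a CLI (`yrbsprev --help`):

```bash
yrbsprev simulate --config cfg.yaml --seed 7 --out runs/sim
yrbsprev evaluate --config cfg.yaml --seed 7 --out runs/eval
yrbsprev predict  --config cfg.yaml --seed 7 --out runs/pred
yrbsprev report   --estimates runs/pred/state_estimates.csv \
                  --evaluation runs/eval/evaluation_report.csv --out runs/report
```

`cfg.yaml` holds the generator settings, file paths, model families, tasks,
and interval level; every run writes a `manifest.yaml` recording the resolved
configuration and seed.

## Reproduction

All randomness is driven by explicit integer seeds: the same seed produces
byte-identical survey CSVs and identical model predictions.  To reproduce
the end-to-end summary quantities (LOO ICCs, interval coverage, mean
absolute errors in percentage points, the identity-above-contact ordering
fraction, and parameter recovery against the generator truth):

```bash
python scripts/acceptance.py --seed 1 --out results.json
```

which writes each quantity as `{"<name>": {"value": ..., "n": ...}}`.  The
acceptance criteria themselves are encoded one-to-one in
`tests/test_acceptance.py`.
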