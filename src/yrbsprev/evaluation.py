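"""Leave-one-state-out evaluation, agreement metrics, and model selection.

The central routine, :func:`loo_state_cv`, evaluates a model family on one
prediction task by holding out each state in turn: the individual-level model
is trained (registry, modal map, and any hyperparameter tuning included) on
the other states only, its predictions for the held-out state are aggregated
with the survey weights, and a prediction interval is built from the *other*
evaluated states' residuals.  The held-out state therefore never contributes
rows to its own training data nor its own residual to its own interval; both
facts are asserted on every run and exposed in the diagnostics.

Three prediction tasks mirror the data configurations a target state can be
in: same-year data with the other focal outcome as a predictor, same-year data
without it, and previous-year data without it.

Agreement between predicted and observed state proportions is measured with
the intraclass correlation coefficient ICC(2,1) — two-way random effects,
absolute agreement, single measurement — with a p-value from the
corresponding F test, plus interval coverage and mean absolute error in
percentage points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import align_to_registry, encode_features
from .model_zoo import (
    ModelSpec,
    fit_model,
    make_state_folds,
    predict_probabilities,
    tune_hyperparameters,
)
from .outcome_coding import OUTCOME_NAMES, OutcomeTable
from .state_estimation import (
    TASKS,
    StateEstimate,
    compute_error_distribution,
    prediction_interval,
    weighted_state_proportion,
)
from .survey_data import SurveyDataset

__all__ = [
    "EvaluationError",
    "LooResult",
    "EvaluationReport",
    "OTHER_OUTCOME",
    "assign_tasks",
    "loo_state_cv",
    "icc",
    "interval_coverage",
    "mean_absolute_error_pp",
    "select_best_model",
    "ordering_check",
    "predictor_sweep",
    "evaluate_models",
    "predict_unobserved_states",
]

logger = logging.getLogger("yrbsprev")

OTHER_OUTCOME = {
    "lgb_identity": "same_sex_contact",
    "same_sex_contact": "lgb_identity",
}

# fixed preference order for ICC ties; the random forest is preferred because
# its agreement was the strongest in nearly every comparison
TIE_BREAK_ORDER = (
    "random_forest",
    "gbrt",
    "lasso_logistic",
    "lasso_linear",
    "ridge_logistic",
    "ridge_linear",
    "logistic",
    "ols",
)


class EvaluationError(ValueError):
    """Raised when an evaluation precondition fails (too few states, etc.)."""


# ---------------------------------------------------------------------------
# Task assignment
# ---------------------------------------------------------------------------


def assign_tasks(
    dataset: SurveyDataset,
    outcomes: OutcomeTable,
    state_id: str,
    outcome_name: str,
    mode: str = "evaluate",
) -> set[str]:
    """Feasible prediction tasks for one state and outcome.

    In ``evaluate`` mode the state must have the outcome observed in the
    target (most recent) year so the prediction can be scored; task 3 is then
    feasible when the state *also* has an earlier survey to predict from.  In
    ``predict`` mode the state is a prediction target (outcome unobserved in
    its most recent survey): tasks 1/2 need target-year data (task 1
    additionally the other focal question there), task 3 applies when the
    state has only pre-target data.  Only the most recent eligible year feeds
    each task.
    """
    if mode not in ("evaluate", "predict"):
        raise EvaluationError(f"unknown mode {mode!r}")
    if outcome_name not in OUTCOME_NAMES:
        raise EvaluationError(f"unknown outcome {outcome_name!r}")
    other = OTHER_OUTCOME[outcome_name]
    target_year = max(dataset.years)
    years = dataset.state_years(state_id)
    if not years:
        return set()
    has_target = target_year in years
    earlier = [y for y in years if y < target_year]

    def avail(year: int, name: str) -> bool:
        return outcomes.available(state_id, year, name)

    tasks: set[str] = set()
    if mode == "evaluate":
        if not (has_target and avail(target_year, outcome_name)):
            return set()
        if avail(target_year, other):
            tasks.add("same_year_with_other")
        tasks.add("same_year_without_other")
        if earlier:
            tasks.add("prev_year_without_other")
    else:
        observed = has_target and avail(target_year, outcome_name)
        if observed:
            return set()
        if has_target:
            tasks.add("same_year_without_other")
            if avail(target_year, other):
                tasks.add("same_year_with_other")
        elif earlier:
            tasks.add("prev_year_without_other")
    return tasks


# ---------------------------------------------------------------------------
# Leave-one-state-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class LooResult:
    """Per-state LOO output for one (family, outcome, task) combination."""

    outcome: str
    task: str
    family: str
    estimates: list[StateEstimate]
    observed: dict[str, float]
    residuals: dict[str, float]
    diagnostics: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "state_id": e.state_id,
                "outcome": e.outcome,
                "task": e.task,
                "point": e.point,
                "lower": e.interval_lower,
                "upper": e.interval_upper,
                "n_respondents": e.n_respondents,
                "model_family": e.model_family,
                "observed": self.observed[e.state_id],
            }
            for e in self.estimates
        ]
        return pd.DataFrame(rows)


def _training_mask(
    dataset: SurveyDataset,
    outcomes: OutcomeTable,
    outcome_name: str,
    exclude_state: str | None,
    require_other: bool,
) -> np.ndarray:
    """Rows usable for training: outcome observed in their cell, not the held-out state."""
    other = OTHER_OUTCOME[outcome_name]
    ok_cells = {
        cell
        for cell in dataset.availability
        if outcomes.available(cell[0], cell[1], outcome_name)
        and (not require_other or outcomes.available(cell[0], cell[1], other))
    }
    keys = list(zip(dataset.data["state_id"], dataset.data["year"].astype(int)))
    mask = np.array([k in ok_cells for k in keys], dtype=bool)
    if exclude_state is not None:
        mask &= (dataset.data["state_id"] != exclude_state).to_numpy()
    return mask


def _fit_on_training(
    dataset: SurveyDataset,
    outcomes: OutcomeTable,
    spec: ModelSpec,
    outcome_name: str,
    train_mask: np.ndarray,
    with_other: bool,
    n_tune_folds: int,
):
    """Encode, tune (state-blocked, nested), and fit on the masked rows."""
    train_ds = dataset.select_rows(train_mask)
    train_out = outcomes.select_rows(train_mask)
    X, registry = encode_features(
        train_ds,
        train_out,
        include_other_outcome=with_other,
        other_outcome_name=OTHER_OUTCOME[outcome_name] if with_other else None,
    )
    y = train_out.table[outcome_name].to_numpy(dtype=np.float64)
    if len(spec.grid_points()) > 1:
        train_states = train_ds.states
        n_folds = min(n_tune_folds, len(train_states))
        fold_of_state = make_state_folds(train_states, n_folds, spec.seed)
        fold_of_row = train_ds.data["state_id"].map(fold_of_state).to_numpy()
        hp = tune_hyperparameters(spec, X, y, registry, fold_of_row)
    else:
        hp = spec.grid_points()[0]
    model = fit_model(spec, hp, X, y, registry)
    return model, registry, train_ds.states


def loo_state_cv(
    dataset: SurveyDataset,
    outcomes: OutcomeTable,
    spec: ModelSpec,
    task: str,
    outcome_name: str,
    level: float = 0.95,
    n_tune_folds: int = 3,
) -> LooResult:
    """Leave-one-state-out evaluation of one family on one task.

    For every state with the outcome observed under the task: train on all
    other states' outcome-observed rows (registry and modal map from training
    data only, hyperparameters tuned by nested state-blocked CV), predict the
    held-out state's task-appropriate survey, aggregate with the survey
    weights, and build the interval from the other evaluated states'
    residuals.  Observed proportions are the weighted proportions of the coded
    outcome in the state's target-year survey.
    """
    if task not in TASKS:
        raise EvaluationError(f"unknown task {task!r}")
    target_year = max(dataset.years)
    with_other = task == "same_year_with_other"
    eligible = [
        s
        for s in dataset.states
        if task in assign_tasks(dataset, outcomes, s, outcome_name, mode="evaluate")
    ]
    if len(eligible) < 3:
        raise EvaluationError(
            f"need >= 3 evaluable states for task {task!r}, found {len(eligible)}"
        )
    logger.info(
        "LOO %s/%s/%s: %d evaluable states", spec.family, outcome_name, task, len(eligible)
    )

    points: dict[str, float] = {}
    observed: dict[str, float] = {}
    n_resp: dict[str, int] = {}
    diagnostics: dict[str, dict] = {}

    state_col = dataset.data["state_id"].to_numpy()
    year_col = dataset.data["year"].to_numpy(dtype=int)

    for s in eligible:
        train_mask = _training_mask(dataset, outcomes, outcome_name, s, with_other)
        model, registry, train_states = _fit_on_training(
            dataset, outcomes, spec, outcome_name, train_mask, with_other, n_tune_folds
        )
        assert s not in train_states, "held-out state leaked into training rows"

        if task == "prev_year_without_other":
            pred_year = max(y for y in dataset.state_years(s) if y < target_year)
        else:
            pred_year = target_year
        cell_mask = (state_col == s) & (year_col == pred_year)
        cell_ds = dataset.select_rows(cell_mask)
        cell_out = outcomes.select_rows(cell_mask)
        Xp = align_to_registry(cell_ds, cell_out if with_other else None, registry)
        probs = predict_probabilities(model, Xp)
        w_pred = cell_ds.data["weight"].to_numpy()
        points[s] = weighted_state_proportion(probs, w_pred)
        n_resp[s] = int(cell_mask.sum())

        obs_mask = (state_col == s) & (year_col == target_year)
        w_obs = dataset.data.loc[obs_mask, "weight"].to_numpy()
        y_obs = outcomes.table.loc[obs_mask, outcome_name].to_numpy(dtype=np.float64)
        observed[s] = weighted_state_proportion(y_obs, w_obs)
        diagnostics[s] = {
            "train_states": tuple(train_states),
            "n_train_rows": int(train_mask.sum()),
            "pred_year": pred_year,
            "hyperparameters": model.hyperparameters,
        }

    residuals = {s: observed[s] - points[s] for s in eligible}
    estimates: list[StateEstimate] = []
    for s in eligible:
        pool = [residuals[t] for t in eligible if t != s]
        pool_states = tuple(t for t in eligible if t != s)
        dist = compute_error_distribution(pool)
        lo, hi = prediction_interval(points[s], dist, level=level)
        assert s not in pool_states, "state's own residual leaked into its interval"
        diagnostics[s]["residual_pool_states"] = pool_states
        estimates.append(
            StateEstimate(
                state_id=s,
                outcome=outcome_name,
                task=task,
                point=points[s],
                interval_lower=lo,
                interval_upper=hi,
                n_respondents=n_resp[s],
                model_family=spec.family,
                source="predicted",
            )
        )
    return LooResult(outcome_name, task, spec.family, estimates, observed, residuals, diagnostics)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def icc(predicted: Sequence[float], observed: Sequence[float]) -> tuple[float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    Computed from the mean squares of the paired (state x rater) table with
    raters {predicted, observed}; the p-value is the one-sided F test of
    ICC > 0 with F = MSR/MSE on (n-1, (n-1)(k-1)) degrees of freedom.  Values
    below -1 are truncated to -1.
    """
    from scipy import stats

    x = np.asarray(predicted, dtype=np.float64)
    y = np.asarray(observed, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise EvaluationError("predicted and observed must be equal-length vectors")
    n = x.size
    if n < 3:
        raise EvaluationError("ICC needs at least 3 paired values")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise EvaluationError("ICC undefined: no variance in either vector")
    value = float((msr - mse) / denom)
    value = max(value, -1.0)
    if mse == 0:
        p_value = 0.0 if msr > 0 else 1.0
    else:
        f_stat = msr / mse
        p_value = float(stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    return value, p_value


def interval_coverage(frame: pd.DataFrame) -> float:
    """Fraction of states whose observed proportion lies in the closed interval."""
    if len(frame) == 0:
        raise EvaluationError("no estimates to score")
    inside = (frame["observed"] >= frame["lower"]) & (frame["observed"] <= frame["upper"])
    return float(inside.mean())


def mean_absolute_error_pp(frame: pd.DataFrame) -> float:
    """Mean |predicted - observed| in percentage points."""
    if len(frame) == 0:
        raise EvaluationError("no estimates to score")
    return float(np.mean(np.abs(frame["point"] - frame["observed"])) * 100.0)


@dataclass
class EvaluationReport:
    """Tables-2/3-shaped metric table plus the per-outcome selected family."""

    frame: pd.DataFrame  # outcome, task, family, icc, icc_p, coverage, mae_pp, n_states
    selected: dict[str, str] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def select_best_model(
    frame: pd.DataFrame, primary_task: str = "same_year_with_other"
) -> dict[str, str]:
    """Highest-ICC family per outcome; ties prefer the fixed family order.

    The primary criterion is the ICC on the with-other-outcome task; outcomes
    evaluated only on other tasks fall back to their best available task.
    """
    if len(frame) == 0:
        raise EvaluationError("empty evaluation report")
    selected: dict[str, str] = {}
    for outcome, sub in frame.groupby("outcome"):
        use = sub[sub["task"] == primary_task]
        if use.empty:
            use = sub
        best_icc = use["icc"].max()
        tied = use.loc[np.isclose(use["icc"], best_icc), "family"].tolist()
        ranked = sorted(
            tied,
            key=lambda f: TIE_BREAK_ORDER.index(f) if f in TIE_BREAK_ORDER else len(TIE_BREAK_ORDER),
        )
        selected[str(outcome)] = ranked[0]
    return selected


def ordering_check(
    lgb_frame: pd.DataFrame, contact_frame: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Per-state check that the identity proportion strictly exceeds the contact one.

    Takes two frames with ``state_id`` and ``point`` columns over the same
    state set; returns the per-state boolean report and the summary fraction.
    The estimates themselves are never modified.
    """
    lgb = lgb_frame.set_index("state_id")["point"]
    ct = contact_frame.set_index("state_id")["point"]
    if set(lgb.index) != set(ct.index):
        raise EvaluationError("ordering check requires matching state sets")
    ct = ct.reindex(lgb.index)
    report = pd.DataFrame(
        {
            "state_id": lgb.index,
            "lgb_point": lgb.to_numpy(),
            "contact_point": ct.to_numpy(),
            "lgb_greater": lgb.to_numpy() > ct.to_numpy(),
        }
    ).reset_index(drop=True)
    return report, float(report["lgb_greater"].mean())


# ---------------------------------------------------------------------------
# Predictor-count sweep
# ---------------------------------------------------------------------------


def _blocked_cv_loss(
    dataset: SurveyDataset,
    outcomes: OutcomeTable,
    spec: ModelSpec,
    outcome_name: str,
    predictor_ids: tuple[str, ...],
    n_folds: int,
    seed: int,
) -> float:
    """State-blocked CV Brier loss with a restricted raw-predictor set."""
    mask = _training_mask(dataset, outcomes, outcome_name, None, False)
    ds = dataset.select_rows(mask)
    out = outcomes.select_rows(mask)
    y = out.table[outcome_name].to_numpy(dtype=np.float64)
    fold_of_state = make_state_folds(ds.states, n_folds, seed)
    fold_of_row = ds.data["state_id"].map(fold_of_state).to_numpy()
    losses = []
    for f in sorted(set(fold_of_state.values())):
        val = fold_of_row == f
        train_ds = ds.select_rows(~val)
        train_out = out.select_rows(~val)
        X, registry = encode_features(train_ds, train_out, predictor_ids=predictor_ids)
        ytr = train_out.table[outcome_name].to_numpy(dtype=np.float64)
        model = fit_model(spec, spec.grid_points()[0], X, ytr, registry)
        val_ds = ds.select_rows(val)
        Xv = align_to_registry(val_ds, None, registry)
        p = predict_probabilities(model, Xv)
        losses.append(float(np.mean((p - y[val]) ** 2)))
    return float(np.mean(losses))


def predictor_sweep(
    dataset: SurveyDataset,
    outcomes: OutcomeTable,
    specs: Sequence[ModelSpec],
    predictor_counts: Sequence[int],
    seed: int,
    outcome_name: str = "lgb_identity",
    n_folds: int = 4,
) -> pd.DataFrame:
    """Blocked-CV loss per family as a function of the number of predictors.

    For each count ``k`` a random subset of ``k`` non-focal questions (shared
    across families) forms the raw-predictor set; ``k = 0`` reduces every
    family to the intercept-only model.  Returns a tidy frame
    ``family, n_predictors, cv_loss``.
    """
    non_focal = tuple(
        q.question_id for q in dataset.catalog.questions if not q.is_focal
    )
    if max(predictor_counts) > len(non_focal):
        raise EvaluationError("predictor count exceeds available questions")
    rng = np.random.default_rng(seed)
    rows = []
    for k in predictor_counts:
        chosen = tuple(sorted(rng.choice(non_focal, size=k, replace=False)))
        for spec in specs:
            loss = _blocked_cv_loss(
                dataset, outcomes, spec, outcome_name, chosen, n_folds, seed
            )
            rows.append({"family": spec.family, "n_predictors": int(k), "cv_loss": loss})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Final state-level estimates
# ---------------------------------------------------------------------------

_TASK_PRIORITY = ("same_year_with_other", "same_year_without_other", "prev_year_without_other")


def predict_unobserved_states(
    dataset: SurveyDataset,
    outcomes: OutcomeTable,
    spec: ModelSpec,
    outcome_name: str,
    level: float = 0.95,
    n_tune_folds: int = 3,
) -> pd.DataFrame:
    """Final estimates table: observed proportions where available, else predictions.

    States with the outcome observed in their most recent survey contribute
    their weighted observed proportion (``source="observed"``).  For each
    remaining state the model is trained on all outcome-observed states, the
    best feasible task is applied (with-other > without-other > previous
    year), and the interval uses the residual pool of that task's LOO run over
    the observed states.  States with no usable data for any task are reported
    with ``source="not_estimable"``.
    """
    target_year = max(dataset.years)
    state_col = dataset.data["state_id"].to_numpy()
    year_col = dataset.data["year"].to_numpy(dtype=int)

    rows: list[dict] = []
    predict_states: dict[str, str] = {}
    for s in dataset.states:
        tasks = assign_tasks(dataset, outcomes, s, outcome_name, mode="predict")
        if tasks:
            predict_states[s] = next(t for t in _TASK_PRIORITY if t in tasks)
            continue
        years = dataset.state_years(s)
        recent = max(years)
        if recent == target_year and outcomes.available(s, recent, outcome_name):
            obs_mask = (state_col == s) & (year_col == recent)
            w = dataset.data.loc[obs_mask, "weight"].to_numpy()
            y = outcomes.table.loc[obs_mask, outcome_name].to_numpy(dtype=np.float64)
            rows.append(
                {
                    "state_id": s,
                    "outcome": outcome_name,
                    "task": "",
                    "point": weighted_state_proportion(y, w),
                    "lower": np.nan,
                    "upper": np.nan,
                    "n_respondents": int(obs_mask.sum()),
                    "model_family": "",
                    "source": "observed",
                }
            )
        else:
            rows.append(
                {
                    "state_id": s,
                    "outcome": outcome_name,
                    "task": "",
                    "point": np.nan,
                    "lower": np.nan,
                    "upper": np.nan,
                    "n_respondents": 0,
                    "model_family": "",
                    "source": "not_estimable",
                }
            )

    # residual pools per needed task, from LOO over the observed states
    pools: dict[str, list[float]] = {}
    for task in set(predict_states.values()):
        res = loo_state_cv(
            dataset, outcomes, spec, task, outcome_name,
            level=level, n_tune_folds=n_tune_folds,
        )
        pools[task] = list(res.residuals.values())

    with_other_mask_cache: dict[bool, np.ndarray] = {}
    for s, task in predict_states.items():
        with_other = task == "same_year_with_other"
        if with_other not in with_other_mask_cache:
            with_other_mask_cache[with_other] = _training_mask(
                dataset, outcomes, outcome_name, None, with_other
            )
        train_mask = with_other_mask_cache[with_other].copy()
        train_mask &= state_col != s  # trivially true for unobserved states
        model, registry, train_states = _fit_on_training(
            dataset, outcomes, spec, outcome_name, train_mask, with_other, n_tune_folds
        )
        assert s not in train_states
        if task == "prev_year_without_other":
            pred_year = max(dataset.state_years(s))
        else:
            pred_year = target_year
        cell_mask = (state_col == s) & (year_col == pred_year)
        cell_ds = dataset.select_rows(cell_mask)
        cell_out = outcomes.select_rows(cell_mask)
        Xp = align_to_registry(cell_ds, cell_out if with_other else None, registry)
        probs = predict_probabilities(model, Xp)
        point = weighted_state_proportion(probs, cell_ds.data["weight"].to_numpy())
        dist = compute_error_distribution(pools[task])
        lo, hi = prediction_interval(point, dist, level=level)
        rows.append(
            {
                "state_id": s,
                "outcome": outcome_name,
                "task": task,
                "point": point,
                "lower": lo,
                "upper": hi,
                "n_respondents": int(cell_mask.sum()),
                "model_family": spec.family,
                "source": "predicted",
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("state_id", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Full evaluation driver
# ---------------------------------------------------------------------------


def evaluate_models(
    dataset: SurveyDataset,
    outcomes: OutcomeTable,
    families: Sequence[str],
    tasks: Sequence[str] = TASKS,
    outcome_names: Sequence[str] = OUTCOME_NAMES,
    grids: Mapping[str, dict] | None = None,
    level: float = 0.95,
    seed: int = 0,
    n_tune_folds: int = 3,
) -> tuple[EvaluationReport, dict[tuple[str, str, str], LooResult]]:
    """Run LOO for every (family x outcome x task); infeasible tasks are skipped.

    ``grids`` optionally maps family names to hyperparameter grids (empty grid
    = fit at the library defaults, no nested tuning).  Returns the metric
    report and the raw LOO results keyed by (outcome, task, family).
    """
    rows = []
    results: dict[tuple[str, str, str], LooResult] = {}
    for outcome_name in outcome_names:
        for family in families:
            grid = dict(grids.get(family, {})) if grids else {}
            spec = ModelSpec(family, grid=grid, seed=seed)
            for task in tasks:
                try:
                    res = loo_state_cv(
                        dataset, outcomes, spec, task, outcome_name,
                        level=level, n_tune_folds=n_tune_folds,
                    )
                except EvaluationError as exc:
                    logger.warning(
                        "skipping %s/%s/%s: %s", family, outcome_name, task, exc
                    )
                    continue
                frame = res.to_frame()
                icc_val, icc_p = icc(frame["point"], frame["observed"])
                rows.append(
                    {
                        "outcome": outcome_name,
                        "task": task,
                        "family": family,
                        "icc": icc_val,
                        "icc_p": icc_p,
                        "coverage": interval_coverage(frame),
                        "mae_pp": mean_absolute_error_pp(frame),
                        "n_states": len(frame),
                    }
                )
                results[(outcome_name, task, family)] = res
    report_frame = pd.DataFrame(rows)
    selected = select_best_model(report_frame) if len(report_frame) else {}
    for outcome_name, family in selected.items():
        logger.info("selected family for %s: %s", outcome_name, family)
    return EvaluationReport(report_frame, selected), results
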