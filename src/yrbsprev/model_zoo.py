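"""The eight individual-level model families, tuning, and importance scores.

Families: ordinary least squares, logistic regression, lasso/ridge penalized
variants of both, a random-forest regressor, and gradient-boosted regression
trees with a logistic objective.  All families predict a probability for a
binary outcome; linear-link families are clipped to [0, 1].

Hyperparameters are tuned by state-blocked n-fold cross-validation: every
respondent of a state lands in the same fold, so the tuning criterion — mean
squared error of predicted probability against the 0/1 outcome (the Brier
score) — measures between-state generalization, which is what the state-level
prediction task requires.
"""

from __future__ import annotations

import itertools
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression, Ridge
from sklearn.ensemble import RandomForestRegressor
from lightgbm import LGBMClassifier

from .features import FeatureRegistry

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "FittedModel",
    "default_grid",
    "make_state_folds",
    "tune_hyperparameters",
    "fit_model",
    "predict_probabilities",
    "permutation_importance",
]

MODEL_FAMILIES = (
    "ols",
    "logistic",
    "lasso_linear",
    "lasso_logistic",
    "ridge_linear",
    "ridge_logistic",
    "random_forest",
    "gbrt",
)

_PENALIZED = ("lasso_linear", "lasso_logistic", "ridge_linear", "ridge_logistic")

_GRID_KEYS = {
    "ols": set(),
    "logistic": set(),
    **{f: {"lambda"} for f in _PENALIZED},
    "random_forest": {"max_depth", "n_trees", "max_features_per_split"},
    "gbrt": {"max_depth", "n_trees", "learning_rate", "max_features_per_split"},
}


@contextmanager
def _quiet_estimators():
    """Silence backend chatter about missing feature names on plain arrays."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*does not have valid feature names.*", category=UserWarning
        )
        yield


def default_grid(family: str) -> dict[str, list]:
    """Standard search grids; the un-penalized families have none to tune."""
    if family in ("ols", "logistic"):
        return {}
    if family in _PENALIZED:
        return {"lambda": list(np.logspace(-4, 1, 8))}
    if family == "random_forest":
        return {
            "max_depth": [8, 16],
            "n_trees": [200],
            "max_features_per_split": ["sqrt"],
        }
    if family == "gbrt":
        return {
            "max_depth": [4, 8],
            "n_trees": [400],
            "learning_rate": [0.1],
            "max_features_per_split": [1.0, "sqrt"],
        }
    raise ValueError(f"unknown family {family!r}")


@dataclass
class ModelSpec:
    """A model family, its hyperparameter grid, and the other-outcome switch."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)
    include_other_outcome: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        bad = set(self.grid) - _GRID_KEYS[self.family]
        if bad:
            raise ValueError(f"grid keys {sorted(bad)} invalid for family {self.family!r}")

    def grid_points(self) -> list[dict]:
        """Grid points in declared order (insertion order of keys and values)."""
        if not self.grid:
            return [{}]
        keys = list(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(self.grid[k] for k in keys))]


@dataclass
class FittedModel:
    family: str
    hyperparameters: dict
    estimator: object
    registry: FeatureRegistry
    kind: str  # "regressor" | "classifier" | "constant"
    constant_value: float | None = None


def make_state_folds(states: Sequence[str], n_folds: int, seed: int) -> dict[str, int]:
    """Assign each state to exactly one fold, balanced to within one state."""
    states = list(states)
    if n_folds > len(states):
        raise ValueError(f"n_folds={n_folds} exceeds the number of states ({len(states)})")
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(states))
    return {states[idx]: i % n_folds for i, idx in enumerate(order)}


def _make_estimator(family: str, hp: Mapping, seed: int, n_features: int):
    if family == "ols":
        return LinearRegression()
    if family == "logistic":
        return LogisticRegression(C=np.inf, max_iter=2000)
    if family in _PENALIZED:
        lam = float(hp["lambda"])
        if family == "lasso_linear":
            return Lasso(alpha=max(lam, 1e-12), max_iter=5000)
        if family == "ridge_linear":
            return Ridge(alpha=lam)
        C = 1.0 / max(lam, 1e-12)
        if family == "lasso_logistic":
            return LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000)
        return LogisticRegression(l1_ratio=0.0, C=C, max_iter=2000)
    if family == "random_forest":
        return RandomForestRegressor(
            n_estimators=int(hp.get("n_trees", 200)),
            max_depth=hp.get("max_depth"),
            max_features=hp.get("max_features_per_split", "sqrt"),
            random_state=seed,
            n_jobs=1,
        )
    if family == "gbrt":
        mf = hp.get("max_features_per_split", "sqrt")
        frac = float(np.sqrt(n_features) / n_features) if mf == "sqrt" else float(mf)
        depth = hp.get("max_depth")
        return LGBMClassifier(
            n_estimators=int(hp.get("n_trees", 200)),
            learning_rate=float(hp.get("learning_rate", 0.1)),
            max_depth=-1 if depth is None else int(depth),
            colsample_bynode=min(max(frac, 1.0 / n_features), 1.0),
            random_state=seed,
            n_jobs=1,
            verbosity=-1,
        )
    raise ValueError(f"unknown family {family!r}")


def fit_model(
    spec: ModelSpec,
    hyperparameters: Mapping,
    X: np.ndarray,
    y: np.ndarray,
    registry: FeatureRegistry,
) -> FittedModel:
    """Fit one family on all supplied rows; deterministic given ``spec.seed``.

    A degenerate outcome (all 0 or all 1) yields a constant model rather than
    an error, since held-out training folds can be one-class.
    """
    y = np.asarray(y, dtype=np.float64)
    # degenerate outcome or an empty predictor set: the honest fit is constant
    if X.shape[1] == 0 or len(np.unique(y)) < 2:
        return FittedModel(spec.family, dict(hyperparameters), None, registry,
                           "constant", float(y.mean()) if len(y) else 0.0)
    est = _make_estimator(spec.family, hyperparameters, spec.seed, X.shape[1])
    is_classifier = spec.family in ("logistic", "lasso_logistic", "ridge_logistic", "gbrt")
    with _quiet_estimators():
        if is_classifier:
            est.fit(X, y.astype(np.int64))
            kind = "classifier"
        else:
            est.fit(X, y)
            kind = "regressor"
    return FittedModel(spec.family, dict(hyperparameters), est, registry, kind)


def predict_probabilities(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Per-respondent probability in [0, 1]; linear outputs are clipped."""
    if X.shape[1] != model.registry.n_columns:
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns, registry expects {model.registry.n_columns}"
        )
    if model.kind == "constant":
        return np.full(X.shape[0], model.constant_value, dtype=np.float64)
    with _quiet_estimators():
        if model.kind == "classifier":
            return model.estimator.predict_proba(X)[:, 1]
        return np.clip(model.estimator.predict(X), 0.0, 1.0)


def tune_hyperparameters(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    registry: FeatureRegistry,
    fold_of_row: np.ndarray,
) -> dict:
    """State-blocked CV over the grid; lowest mean Brier score wins, first on ties.

    ``fold_of_row`` assigns every training row to the fold of its state (see
    :func:`make_state_folds`).  Families with an empty grid return the empty
    setting without running CV.
    """
    points = spec.grid_points()
    if len(points) == 1:
        return points[0]
    folds = np.unique(fold_of_row)
    y = np.asarray(y, dtype=np.float64)
    best_point, best_mse = None, np.inf
    for point in points:
        fold_mses = []
        for f in folds:
            val = fold_of_row == f
            model = fit_model(spec, point, X[~val], y[~val], registry)
            p = predict_probabilities(model, X[val])
            fold_mses.append(float(np.mean((p - y[val]) ** 2)))
            # integrity: the validation fold contributes no training rows
            assert f not in np.unique(fold_of_row[~val])
        mse = float(np.mean(fold_mses))
        if mse < best_mse - 1e-15:
            best_point, best_mse = point, mse
    return best_point


def permutation_importance(
    model: FittedModel,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-question block-permutation importance, sorted descending.

    All of a question's columns (level indicators plus the missing indicator)
    are permuted jointly with the same row permutation, so the score reflects
    the question as the survey reports it.  Importance is the mean increase in
    prediction mean squared error over ``n_repeats`` permutations; the other-
    outcome column, when present, is scored as its own block.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=np.float64)
    base = float(np.mean((predict_probabilities(model, X) - y) ** 2))
    blocks: list[tuple[str, np.ndarray]] = []
    for qid in model.registry.question_ids:
        blocks.append((qid, model.registry.question_column_indices(qid)))
    if model.registry.other_outcome is not None:
        j = model.registry.n_columns - 1
        blocks.append((f"other_outcome:{model.registry.other_outcome}", np.array([j])))
    rows = []
    for qid, idx in blocks:
        increases = []
        for _ in range(n_repeats):
            perm = rng.permutation(X.shape[0])
            Xp = X.copy()
            Xp[:, idx] = X[perm][:, idx]
            mse = float(np.mean((predict_probabilities(model, Xp) - y) ** 2))
            increases.append(mse - base)
        rows.append((qid, float(np.mean(increases))))
    out = pd.DataFrame(rows, columns=["question_id", "importance"])
    out = out.sort_values("importance", ascending=False, kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
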