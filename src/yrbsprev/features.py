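"""Predictor construction: imputation, missingness indicators, and alignment.

Categorical responses are dummy-coded (one indicator per non-reference level,
reference = first catalog level).  A missing response is imputed to the modal
response of the training data before dummy expansion, and every question also
contributes one missingness-indicator column, so the encoded matrix is always
complete.  A question that a prediction state never asked is simply a question
whose responses are all missing, and is handled by the same mechanism.

Train/predict column agreement is guaranteed by a :class:`FeatureRegistry`:
the ordered column list plus the modal map, built on training data and applied
verbatim when encoding any other data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .outcome_coding import OUTCOME_NAMES, OutcomeTable
from .survey_data import QuestionCatalog, SurveyDataset, SurveyValidationError

__all__ = [
    "FeatureColumn",
    "FeatureRegistry",
    "predictor_question_ids",
    "compute_modal_responses",
    "encode_features",
    "align_to_registry",
]


class AlignmentError(ValueError):
    """Registry and data disagree on a question or level."""


@dataclass(frozen=True)
class FeatureColumn:
    question_id: str
    kind: str  # "level-indicator" | "missing-indicator" | "other-outcome"
    level: int | None = None


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered feature columns plus the modal-imputation map.

    ``other_outcome`` names the focal outcome appended as a single 0/1 column,
    or is None when the model excludes it.
    """

    columns: tuple[FeatureColumn, ...]
    modal_map: dict[str, int]
    other_outcome: str | None = None

    @property
    def question_ids(self) -> tuple[str, ...]:
        seen = dict.fromkeys(
            c.question_id for c in self.columns if c.kind != "other-outcome"
        )
        return tuple(seen)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def question_column_indices(self, question_id: str) -> np.ndarray:
        """Indices of all columns (level + missing indicators) of one question."""
        return np.array(
            [i for i, c in enumerate(self.columns)
             if c.question_id == question_id and c.kind != "other-outcome"],
            dtype=np.intp,
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "columns": [
                {"question_id": c.question_id, "kind": c.kind, "level": c.level}
                for c in self.columns
            ],
            "modal_map": {k: int(v) for k, v in self.modal_map.items()},
            "other_outcome": self.other_outcome,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureRegistry":
        payload = yaml.safe_load(Path(path).read_text())
        cols = tuple(
            FeatureColumn(d["question_id"], d["kind"], d["level"])
            for d in payload["columns"]
        )
        return cls(cols, dict(payload["modal_map"]), payload["other_outcome"])


def predictor_question_ids(catalog: QuestionCatalog) -> tuple[str, ...]:
    """Questions usable as raw predictors: everything except the two outcome items.

    The sex question stays in the predictor set: it does not by itself reveal
    either outcome, and dropping it would discard real signal.  The identity
    and contact questions are always excluded (their raw responses determine
    the outcomes); the *coded* other outcome enters separately when a model
    requests it.
    """
    return tuple(
        q.question_id for q in catalog.questions if q.role not in ("identity", "contact")
    )


def compute_modal_responses(dataset: SurveyDataset) -> dict[str, int]:
    """Most frequent non-missing response per question, over all training rows.

    Ties break to the lowest response code; a question with no non-missing
    response maps to its first catalog level.
    """
    modal: dict[str, int] = {}
    for q in dataset.catalog.questions:
        col = dataset.data[q.question_id].dropna()
        if len(col) == 0:
            modal[q.question_id] = int(q.levels[0])
            continue
        counts = Counter(int(v) for v in col)
        best = max(sorted(counts), key=lambda lvl: (counts[lvl], -lvl))
        modal[q.question_id] = int(best)
    return modal


def _build_registry(
    dataset: SurveyDataset,
    include_other_outcome: bool,
    other_outcome_name: str | None,
    predictor_ids: tuple[str, ...] | None = None,
) -> FeatureRegistry:
    if include_other_outcome:
        if other_outcome_name not in OUTCOME_NAMES:
            raise SurveyValidationError(
                f"other_outcome_name must be one of {OUTCOME_NAMES}, got {other_outcome_name!r}"
            )
    modal = compute_modal_responses(dataset)
    columns: list[FeatureColumn] = []
    if predictor_ids is None:
        predictor_ids = predictor_question_ids(dataset.catalog)
    for qid in predictor_ids:
        levels = dataset.catalog[qid].levels
        for lvl in levels[1:]:
            columns.append(FeatureColumn(qid, "level-indicator", int(lvl)))
        columns.append(FeatureColumn(qid, "missing-indicator"))
    other = other_outcome_name if include_other_outcome else None
    if other is not None:
        columns.append(FeatureColumn(other, "other-outcome"))
    return FeatureRegistry(tuple(columns), modal, other)


def _encode_with_registry(
    dataset: SurveyDataset,
    outcomes: OutcomeTable | None,
    registry: FeatureRegistry,
    strict: bool,
) -> np.ndarray:
    """Fill the matrix column-by-column per the registry.

    ``strict`` enforces that every registry question exists in the dataset's
    catalog with compatible levels (training-time contract); the alignment
    path is total instead, treating unknown questions as entirely missing.
    """
    n = len(dataset.data)
    X = np.zeros((n, registry.n_columns), dtype=np.float32)
    values: dict[str, np.ndarray] = {}
    missing: dict[str, np.ndarray] = {}
    for qid in registry.question_ids:
        if qid in dataset.catalog:
            raw = dataset.data[qid].to_numpy(dtype="float64", na_value=np.nan)
            miss = np.isnan(raw)
            filled = np.where(miss, registry.modal_map[qid], raw)
        elif strict:
            raise AlignmentError(f"registry question {qid!r} unknown to the dataset catalog")
        else:
            miss = np.ones(n, dtype=bool)
            filled = np.full(n, registry.modal_map[qid], dtype=np.float64)
        values[qid] = filled
        missing[qid] = miss
        if strict and qid in dataset.catalog:
            reg_levels = {c.level for c in registry.columns
                          if c.question_id == qid and c.kind == "level-indicator"}
            cat_levels = set(dataset.catalog[qid].levels[1:])
            if reg_levels != cat_levels:
                raise AlignmentError(f"level mismatch for question {qid!r}")

    for j, col in enumerate(registry.columns):
        if col.kind == "level-indicator":
            X[:, j] = values[col.question_id] == col.level
        elif col.kind == "missing-indicator":
            X[:, j] = missing[col.question_id]
        else:  # other-outcome
            if outcomes is None:
                raise AlignmentError("other-outcome column requested but no outcomes given")
            X[:, j] = outcomes.table[col.question_id].to_numpy(dtype=np.float32)
    return X


def encode_features(
    dataset: SurveyDataset,
    outcomes: OutcomeTable | None = None,
    registry: FeatureRegistry | None = None,
    include_other_outcome: bool = False,
    other_outcome_name: str | None = None,
    predictor_ids: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, FeatureRegistry]:
    """Encode a dataset into a complete numeric matrix.

    With ``registry=None`` a fresh registry (columns + modal map) is built
    from this dataset, which is then the training encoding; ``predictor_ids``
    optionally restricts the raw-predictor questions (used by the
    predictor-count sweep).  With a registry supplied, columns match it
    exactly and a mismatching catalog raises :class:`AlignmentError`.
    """
    if registry is None:
        registry = _build_registry(
            dataset, include_other_outcome, other_outcome_name, predictor_ids
        )
    X = _encode_with_registry(dataset, outcomes, registry, strict=True)
    return X, registry


def align_to_registry(
    dataset: SurveyDataset,
    outcomes: OutcomeTable | None,
    registry: FeatureRegistry,
) -> np.ndarray:
    """Encode prediction-state data against a training registry; always total.

    Questions the prediction data lacks are treated as missing for every
    respondent (modal-imputed, missing indicator 1); extra questions in the
    data are ignored; column order is the registry's.
    """
    return _encode_with_registry(dataset, outcomes, registry, strict=False)
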