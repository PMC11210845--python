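"""Survey-weighted aggregation and residual-based Student's-t prediction intervals.

Individual predicted probabilities are aggregated to a state proportion with
the survey weights.  Uncertainty comes not from a design-based variance but
from the out-of-sample residuals of the *other* states under the same
prediction task: their mean and sample standard deviation parameterize a
Student's-t error distribution with degrees of freedom equal to the number of
contributing states minus one, and the interval adds that distribution's tail
quantiles to the point estimate.  Residuals follow the convention
``observed - predicted``, so the 2.5th/97.5th error percentiles added to the
point are literally the interval bounds.  Intervals are clipped to [0, 1];
point estimates are never shifted by the mean residual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ErrorDistribution",
    "StateEstimate",
    "TASKS",
    "weighted_state_proportion",
    "compute_error_distribution",
    "prediction_interval",
]

TASKS = ("same_year_with_other", "same_year_without_other", "prev_year_without_other")


@dataclass(frozen=True)
class ErrorDistribution:
    """Location/scale/df of the residual t distribution for one task."""

    location: float
    scale: float
    df: int
    n_source_states: int

    def __post_init__(self) -> None:
        if self.n_source_states < 2:
            raise ValueError("an error distribution needs at least two source states")
        if self.df != self.n_source_states - 1:
            raise ValueError("df must equal n_source_states - 1")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")


@dataclass(frozen=True)
class StateEstimate:
    state_id: str
    outcome: str
    task: str
    point: float
    interval_lower: float
    interval_upper: float
    n_respondents: int
    model_family: str
    source: str = "predicted"  # "observed" | "predicted"


def weighted_state_proportion(
    probabilities: Sequence[float], weights: Sequence[float]
) -> float:
    """Weighted mean sum(w*p)/sum(w) of per-respondent probabilities."""
    p = np.asarray(probabilities, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if p.size == 0 or w.size == 0:
        raise ValueError("empty input")
    if p.shape != w.shape:
        raise ValueError("probabilities and weights must have equal length")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    return float(np.sum(w * p) / np.sum(w))


def compute_error_distribution(residuals: Sequence[float]) -> ErrorDistribution:
    """Mean/sample-SD/df of the other states' (observed - predicted) residuals."""
    r = np.asarray(residuals, dtype=np.float64)
    if r.size < 2:
        raise ValueError("at least two residuals are required for an interval")
    return ErrorDistribution(
        location=float(np.mean(r)),
        scale=float(np.std(r, ddof=1)),
        df=int(r.size - 1),
        n_source_states=int(r.size),
    )


def prediction_interval(
    point: float, error_distribution: ErrorDistribution, level: float = 0.95
) -> tuple[float, float]:
    """Add the error distribution's tail quantiles to the point; clip to [0, 1].

    With zero scale the interval degenerates to ``point + location``.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    d = error_distribution
    alpha = (1 - level) / 2
    if d.scale == 0:
        lo = hi = point + d.location
    else:
        lo = point + stats.t.ppf(alpha, d.df, loc=d.location, scale=d.scale)
        hi = point + stats.t.ppf(1 - alpha, d.df, loc=d.location, scale=d.scale)
    return (float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0)))
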