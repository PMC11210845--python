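"""Shared fixtures: a deterministic hypothesis profile and tiny handcrafted datasets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from yrbsprev import Question, QuestionCatalog, SurveyDataset

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def small_catalog() -> QuestionCatalog:
    """Five-question catalog: the three focal items plus two ordinary questions."""
    return QuestionCatalog(
        (
            Question("sex", (1, 2), role="sex"),
            Question("identity", (1, 2, 3, 4), role="identity"),
            Question("contact", (1, 2, 3, 4), role="contact"),
            Question("q001", (1, 2, 3)),
            Question("q002", (1, 2)),
        )
    )


def build_dataset(rows, availability, catalog=None) -> SurveyDataset:
    """Construct a SurveyDataset from (state, year, weight, sex, identity, contact, q001, q002) tuples.

    Response entries may be None for a missing answer.
    """
    catalog = catalog or small_catalog()
    cols = ["state_id", "year", "weight"] + list(catalog.question_ids)
    df = pd.DataFrame(rows, columns=cols)
    df["year"] = df["year"].astype(int)
    df["weight"] = df["weight"].astype(float)
    for q in catalog.question_ids:
        df[q] = pd.array(df[q], dtype="Int64")
    ds = SurveyDataset(catalog, df, {k: frozenset(v) for k, v in availability.items()})
    ds.validate()
    return ds


ALL_Q = ("sex", "identity", "contact", "q001", "q002")


@pytest.fixture
def tiny_dataset() -> SurveyDataset:
    """Three states x one year, all questions asked, no missingness except where noted."""
    rows = [
        # state A, 2017
        ("A", 2017, 1.0, 1, 2, 2, 1, 1),   # lgb=1 (gay/lesbian), contact=1 (F-F)
        ("A", 2017, 2.0, 2, 1, 1, 2, 2),   # lgb=0, contact=0
        ("A", 2017, 1.0, 2, 3, 4, 3, 1),   # lgb=1 (bisexual), contact=1 (both)
        # state B, 2017
        ("B", 2017, 1.0, 1, 1, 3, 1, 2),   # female x "males" -> 0
        ("B", 2017, 1.0, 2, 4, 3, 2, 1),   # not sure -> 0; male x "males" -> 1
        # state C, 2017
        ("C", 2017, 3.0, 1, 1, 1, None, 2),
        ("C", 2017, 1.0, 2, 2, 2, 1, None),  # male x "females" -> 0
    ]
    avail = {
        ("A", 2017): ALL_Q,
        ("B", 2017): ALL_Q,
        ("C", 2017): ALL_Q,
    }
    return build_dataset(rows, avail)


@pytest.fixture
def multi_year_dataset() -> SurveyDataset:
    """States in the task-assignment example configurations.

    A: 2015+2017, everything asked.  B: 2017 only, contact not asked.  C: 2015
    only.  D: 2017 only, identity not asked (prediction target for identity).
    """
    rows = [
        ("A", 2015, 1.0, 1, 1, 1, 1, 1),
        ("A", 2015, 1.0, 2, 2, 4, 2, 2),
        ("A", 2017, 1.0, 1, 3, 2, 3, 1),
        ("A", 2017, 1.0, 2, 1, 1, 1, 2),
        ("B", 2017, 1.0, 1, 2, None, 2, 1),
        ("B", 2017, 1.0, 2, 1, None, 3, 2),
        ("C", 2015, 1.0, 1, 1, 4, 1, 1),
        ("C", 2015, 1.0, 2, 3, 1, 2, 2),
        ("D", 2017, 1.0, 1, None, 2, 3, 1),
        ("D", 2017, 1.0, 2, None, 3, 1, 2),
    ]
    avail = {
        ("A", 2015): ALL_Q,
        ("A", 2017): ALL_Q,
        ("B", 2017): ("sex", "identity", "q001", "q002"),
        ("C", 2015): ALL_Q,
        ("D", 2017): ("sex", "contact", "q001", "q002"),
    }
    return build_dataset(rows, avail)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
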