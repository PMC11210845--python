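"""Deterministic coding of the two binary focal outcomes.

Coding follows the questionnaire's published rules and is total: a respondent
with a missing response is coded 0, never missing.

* LGB identity: 1 iff the identity answer is "Gay or lesbian" or "Bisexual";
  everything else (heterosexual, not sure, missing) is 0.
* Any same-sex contact: 1 iff the contact answer is "Females and males", or
  the respondent is male and answered "Males", or female and answered
  "Females"; everything else, including a missing sex with a same-sex-specific
  answer, is 0.  Rule (1) does not condition on sex, so a missing-sex
  respondent answering "Females and males" is still coded 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey_data import (
    CONTACT_BOTH,
    CONTACT_FEMALES,
    CONTACT_MALES,
    IDENTITY_BISEXUAL,
    IDENTITY_GAY_LESBIAN,
    SEX_FEMALE,
    SEX_MALE,
    SurveyDataset,
    SurveyValidationError,
)

__all__ = [
    "OutcomeTable",
    "code_lgb_identity",
    "code_same_sex_contact",
    "attach_outcomes",
    "stratify_by_sex",
    "write_outcomes_csv",
]

OUTCOME_NAMES = ("lgb_identity", "same_sex_contact")

_IDENTITY_LEVELS = frozenset((1, 2, 3, 4))
_SEX_LEVELS = frozenset((SEX_FEMALE, SEX_MALE))
_CONTACT_LEVELS = frozenset((1, 2, 3, 4))


@dataclass
class OutcomeTable:
    """Per-respondent 0/1 codings plus per-(state, year) availability flags.

    ``table`` is row-aligned with the source dataset's ``data`` and holds the
    columns ``state_id, year, lgb_identity, same_sex_contact``.
    ``availability`` maps each cell to
    ``{"identity_available": bool, "contact_available": bool}``; contact
    availability requires both the sex and the contact question to have been
    asked.
    """

    table: pd.DataFrame
    availability: dict[tuple[str, int], dict[str, bool]]

    def outcome(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=np.int64)

    def available(self, state_id: str, year: int, name: str) -> bool:
        key = "identity_available" if name == "lgb_identity" else "contact_available"
        return self.availability[(state_id, year)][key]

    def select_rows(self, mask) -> "OutcomeTable":
        table = self.table.loc[np.asarray(mask)].reset_index(drop=True)
        cells = {(str(s), int(y)) for s, y in table[["state_id", "year"]].drop_duplicates().to_numpy()}
        avail = {k: v for k, v in self.availability.items() if k in cells}
        return OutcomeTable(table, avail)


def _check_level(value, allowed: frozenset, what: str) -> None:
    if value is not None and not pd.isna(value) and int(value) not in allowed:
        raise SurveyValidationError(f"{what} response {value!r} outside catalog levels")


def code_lgb_identity(identity_response) -> int:
    """1 iff the response is "Gay or lesbian" or "Bisexual"; missing codes to 0."""
    _check_level(identity_response, _IDENTITY_LEVELS, "identity")
    if identity_response is None or pd.isna(identity_response):
        return 0
    return int(int(identity_response) in (IDENTITY_GAY_LESBIAN, IDENTITY_BISEXUAL))


def code_same_sex_contact(sex_response, contact_response) -> int:
    """Apply the three same-sex-contact rules; any other combination codes to 0."""
    _check_level(sex_response, _SEX_LEVELS, "sex")
    _check_level(contact_response, _CONTACT_LEVELS, "contact")
    if contact_response is None or pd.isna(contact_response):
        return 0
    contact = int(contact_response)
    if contact == CONTACT_BOTH:
        return 1
    if sex_response is None or pd.isna(sex_response):
        return 0
    sex = int(sex_response)
    if sex == SEX_MALE and contact == CONTACT_MALES:
        return 1
    if sex == SEX_FEMALE and contact == CONTACT_FEMALES:
        return 1
    return 0


def attach_outcomes(dataset: SurveyDataset) -> OutcomeTable:
    """Code both outcomes for every respondent and derive availability flags."""
    catalog = dataset.catalog
    try:
        id_q = catalog.identity_question.question_id
        sex_q = catalog.sex_question.question_id
        ct_q = catalog.contact_question.question_id
    except StopIteration as exc:  # pragma: no cover - catalog enforces this
        raise SurveyValidationError("catalog lacks a focal question") from exc

    identity = dataset.data[id_q]
    sex = dataset.data[sex_q]
    contact = dataset.data[ct_q]

    # vectorized equivalents of the scalar coding rules
    lgb = identity.isin((IDENTITY_GAY_LESBIAN, IDENTITY_BISEXUAL)).fillna(False)
    both = contact.eq(CONTACT_BOTH).fillna(False)
    male_males = (sex.eq(SEX_MALE) & contact.eq(CONTACT_MALES)).fillna(False)
    female_females = (sex.eq(SEX_FEMALE) & contact.eq(CONTACT_FEMALES)).fillna(False)
    ssc = both | male_males | female_females

    table = pd.DataFrame(
        {
            "state_id": dataset.data["state_id"].to_numpy(),
            "year": dataset.data["year"].to_numpy(),
            "lgb_identity": lgb.to_numpy(dtype=np.int64),
            "same_sex_contact": ssc.to_numpy(dtype=np.int64),
        }
    )
    availability = {
        cell: {
            "identity_available": id_q in asked,
            "contact_available": (ct_q in asked) and (sex_q in asked),
        }
        for cell, asked in dataset.availability.items()
    }
    return OutcomeTable(table, availability)


def stratify_by_sex(
    dataset: SurveyDataset, outcomes: OutcomeTable, sex_level: str
) -> tuple[SurveyDataset, OutcomeTable]:
    """Restrict to respondents of one recorded sex (missing sex is dropped)."""
    levels = {"Female": SEX_FEMALE, "Male": SEX_MALE}
    if sex_level not in levels:
        raise SurveyValidationError(f"unknown sex_level {sex_level!r}")
    sex_q = dataset.catalog.sex_question.question_id
    mask = dataset.data[sex_q].eq(levels[sex_level]).fillna(False).to_numpy()
    return dataset.select_rows(mask), outcomes.select_rows(mask)


def write_outcomes_csv(outcomes: OutcomeTable, path) -> None:
    """Export ``state_id, year, respondent_index, lgb_identity, same_sex_contact``."""
    df = outcomes.table.copy()
    df.insert(2, "respondent_index", np.arange(len(df)))
    df.to_csv(path, index=False)
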