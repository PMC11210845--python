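"""Survey data model, CSV I/O, summaries, and a synthetic multi-state generator.

The in-memory container for respondent-level survey microdata is a
:class:`SurveyDataset`: a :class:`QuestionCatalog` describing the questionnaire,
a pandas DataFrame with one row per respondent (``state_id``, ``year``,
``weight``, then one nullable-integer column per question), and an availability
map recording which questions each (state, year) survey actually asked.

Because real state-level YRBS microdata are restricted, the module also ships a
synthetic generator that emulates the statistical structure of such data:
30-50 states, 1-3 survey years per state, ~80 categorical questions with
state-varying availability, right-skewed survey weights, item-level
missingness, and two correlated binary focal outcomes (sexual-minority identity
and any same-sex sexual contact) whose between-state prevalence distribution is
calibrated to published state-level moments (mean 9,375 per 100k, SD 1,228 for
the identity outcome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special

__all__ = [
    "MISSING",
    "Question",
    "QuestionCatalog",
    "RespondentRecord",
    "SurveyDataset",
    "GeneratorConfig",
    "generate_synthetic_survey",
    "read_survey_csv",
    "write_survey_csv",
    "read_availability_csv",
    "write_availability_csv",
    "summarize_dataset",
    "subset_questions",
    "default_catalog",
    "calibrate_logit_prevalence",
]

#: Sentinel for an unanswered item.  Responses are stored in pandas nullable
#: integer columns, so missingness is pd.NA, never a response level.
MISSING = pd.NA

# Response level semantics for the three special questions, mirroring the
# questionnaire's letter choices (A=1, B=2, ...).
SEX_FEMALE = 1
SEX_MALE = 2
IDENTITY_HETEROSEXUAL = 1
IDENTITY_GAY_LESBIAN = 2
IDENTITY_BISEXUAL = 3
IDENTITY_NOT_SURE = 4
CONTACT_NEVER = 1
CONTACT_FEMALES = 2
CONTACT_MALES = 3
CONTACT_BOTH = 4

META_COLUMNS = ("state_id", "year", "weight")


class SurveyValidationError(ValueError):
    """Raised when a dataset, config, or file violates the data contract."""


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Question:
    """One questionnaire item: an id, its ordered response levels, and a role.

    ``role`` is ``""`` for ordinary questions, or one of ``"sex"``,
    ``"identity"``, ``"contact"`` for the three focal items.
    """

    question_id: str
    levels: tuple[int, ...]
    role: str = ""

    def __post_init__(self) -> None:
        if not self.levels:
            raise SurveyValidationError(f"question {self.question_id!r} has no levels")
        if self.role not in ("", "sex", "identity", "contact"):
            raise SurveyValidationError(f"unknown role {self.role!r}")

    @property
    def is_focal(self) -> bool:
        return bool(self.role)


@dataclass(frozen=True)
class QuestionCatalog:
    """Ordered collection of questions with exactly one sex/identity/contact item."""

    questions: tuple[Question, ...]

    def __post_init__(self) -> None:
        ids = [q.question_id for q in self.questions]
        if len(set(ids)) != len(ids):
            raise SurveyValidationError("duplicate question ids in catalog")
        for role in ("sex", "identity", "contact"):
            n = sum(1 for q in self.questions if q.role == role)
            if n != 1:
                raise SurveyValidationError(
                    f"catalog must flag exactly one {role} question, found {n}"
                )

    @property
    def question_ids(self) -> tuple[str, ...]:
        return tuple(q.question_id for q in self.questions)

    def __getitem__(self, question_id: str) -> Question:
        for q in self.questions:
            if q.question_id == question_id:
                return q
        raise KeyError(question_id)

    def __contains__(self, question_id: str) -> bool:
        return any(q.question_id == question_id for q in self.questions)

    def question_with_role(self, role: str) -> Question:
        return next(q for q in self.questions if q.role == role)

    @property
    def sex_question(self) -> Question:
        return self.question_with_role("sex")

    @property
    def identity_question(self) -> Question:
        return self.question_with_role("identity")

    @property
    def contact_question(self) -> Question:
        return self.question_with_role("contact")

    def to_yaml(self, path: str | Path) -> None:
        payload = [
            {"question_id": q.question_id, "levels": list(q.levels), "role": q.role}
            for q in self.questions
        ]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QuestionCatalog":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            tuple(
                Question(d["question_id"], tuple(int(v) for v in d["levels"]), d.get("role", ""))
                for d in payload
            )
        )


def default_catalog(n_questions: int = 76, level_counts: Sequence[int] | None = None) -> QuestionCatalog:
    """Standard questionnaire: sex, identity, contact, plus ``n_questions`` others.

    Ordinary questions are named ``q001``... and cycle through a fixed set of
    level counts so the catalog resembles a real mixed questionnaire.
    """
    cycle = tuple(level_counts) if level_counts is not None else (4, 5, 3, 6, 2, 7)
    questions = [
        Question("sex", (SEX_FEMALE, SEX_MALE), role="sex"),
        Question("identity", (1, 2, 3, 4), role="identity"),
        Question("contact", (1, 2, 3, 4), role="contact"),
    ]
    for i in range(n_questions):
        n_levels = cycle[i % len(cycle)]
        questions.append(Question(f"q{i + 1:03d}", tuple(range(1, n_levels + 1))))
    return QuestionCatalog(tuple(questions))


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RespondentRecord:
    """A single respondent; mainly a row view used by :meth:`SurveyDataset.iter_records`."""

    state_id: str
    year: int
    weight: float
    responses: Mapping[str, object]


@dataclass
class SurveyDataset:
    """Respondent table + catalog + per-(state, year) question availability.

    ``data`` holds ``state_id`` (str), ``year`` (int), ``weight`` (float > 0)
    and one ``Int64`` (nullable) column per catalog question.  ``availability``
    maps each (state_id, year) cell to the frozenset of question ids that the
    survey in that cell actually asked; any question outside that set is
    missing for every respondent of the cell.
    """

    catalog: QuestionCatalog
    data: pd.DataFrame
    availability: dict[tuple[str, int], frozenset[str]]

    def validate(self) -> None:
        """Check every dataset invariant; raise :class:`SurveyValidationError` on failure."""
        expected = list(META_COLUMNS) + list(self.catalog.question_ids)
        if list(self.data.columns) != expected:
            raise SurveyValidationError("data columns do not match catalog order")
        w = self.data["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise SurveyValidationError("weights must be positive and finite")
        cells = set(map(tuple, self.data[["state_id", "year"]].drop_duplicates().to_numpy()))
        cells = {(str(s), int(y)) for s, y in cells}
        if set(self.availability) != cells:
            raise SurveyValidationError("availability keys must equal the observed (state, year) cells")
        grouped = self.data.groupby(["state_id", "year"], sort=False)
        for (state, year), chunk in grouped:
            asked = self.availability[(state, int(year))]
            for q in self.catalog.questions:
                col = chunk[q.question_id]
                if q.question_id not in asked:
                    if col.notna().any():
                        raise SurveyValidationError(
                            f"question {q.question_id!r} not asked in {(state, year)} "
                            "but has non-missing responses"
                        )
                else:
                    vals = col.dropna().unique()
                    bad = set(int(v) for v in vals) - set(q.levels)
                    if bad:
                        raise SurveyValidationError(
                            f"responses {sorted(bad)} outside catalog levels for "
                            f"{q.question_id!r} in {(state, year)}"
                        )

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data["state_id"]))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(set(int(y) for y in self.data["year"])))

    def cell(self, state_id: str, year: int) -> pd.DataFrame:
        mask = (self.data["state_id"] == state_id) & (self.data["year"] == year)
        return self.data.loc[mask]

    def state_years(self, state_id: str) -> tuple[int, ...]:
        return tuple(sorted(int(y) for s, y in self.availability if s == state_id))

    def iter_records(self) -> Iterable[RespondentRecord]:
        qids = self.catalog.question_ids
        for row in self.data.itertuples(index=False):
            responses = dict(zip(qids, row[3:]))
            yield RespondentRecord(row.state_id, int(row.year), float(row.weight), responses)

    def select_rows(self, mask: np.ndarray | pd.Series) -> "SurveyDataset":
        """Row-subset with availability restricted to the remaining cells."""
        data = self.data.loc[mask].reset_index(drop=True)
        cells = {(str(s), int(y)) for s, y in data[["state_id", "year"]].drop_duplicates().to_numpy()}
        avail = {k: v for k, v in self.availability.items() if k in cells}
        return SurveyDataset(self.catalog, data, avail)


def subset_questions(dataset: SurveyDataset, keep_ids: Sequence[str]) -> SurveyDataset:
    """Restrict a dataset to ``keep_ids`` non-focal questions (focal ones are kept).

    Used by the predictor-count sweep: the catalog, data columns, and
    availability sets are all reduced consistently.
    """
    keep = set(keep_ids)
    questions = tuple(q for q in dataset.catalog.questions if q.is_focal or q.question_id in keep)
    catalog = QuestionCatalog(questions)
    cols = list(META_COLUMNS) + [q.question_id for q in questions]
    data = dataset.data[cols].copy()
    avail = {
        cell: frozenset(q for q in asked if q in catalog.question_ids)
        for cell, asked in dataset.availability.items()
    }
    return SurveyDataset(catalog, data, avail)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_survey_csv(dataset: SurveyDataset, path: str | Path) -> None:
    """Write one row per respondent; missing responses become empty fields.

    Column order is ``state_id, year, weight`` followed by the catalog's
    question order, so identical datasets serialize byte-identically.
    """
    df = dataset.data.copy()
    df.to_csv(path, index=False, na_rep="")


def read_survey_csv(
    path: str | Path,
    catalog: QuestionCatalog,
    availability: Mapping[tuple[str, int], frozenset[str]] | None = None,
) -> SurveyDataset:
    """Parse a survey CSV against ``catalog``; round-trips :func:`write_survey_csv`.

    Availability is taken from ``availability`` when given; otherwise it is
    inferred with the rule "a question entirely missing within a (state, year)
    cell was not asked there".
    """
    df = pd.read_csv(path, dtype={"state_id": str})
    expected = list(META_COLUMNS) + list(catalog.question_ids)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise SurveyValidationError(f"unknown question column(s) {unknown}")
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise SurveyValidationError(f"missing column(s) {missing_cols}")
    df = df[expected]
    df["year"] = df["year"].astype(int)
    df["weight"] = df["weight"].astype(float)
    bad_w = ~np.isfinite(df["weight"].to_numpy()) | (df["weight"].to_numpy() <= 0)
    if bad_w.any():
        row = int(np.flatnonzero(bad_w)[0])
        raise SurveyValidationError(f"non-positive or non-finite weight at row {row}")
    for q in catalog.questions:
        col = pd.array(df[q.question_id], dtype="Int64")
        vals = set(int(v) for v in col.dropna())
        bad = vals - set(q.levels)
        if bad:
            raise SurveyValidationError(
                f"response code(s) {sorted(bad)} outside catalog levels in column {q.question_id!r}"
            )
        df[q.question_id] = col

    if availability is None:
        avail: dict[tuple[str, int], frozenset[str]] = {}
        for (state, year), chunk in df.groupby(["state_id", "year"], sort=False):
            asked = frozenset(
                q for q in catalog.question_ids if chunk[q].notna().any()
            )
            avail[(str(state), int(year))] = asked
    else:
        avail = {(str(s), int(y)): frozenset(v) for (s, y), v in availability.items()}
    ds = SurveyDataset(catalog, df.reset_index(drop=True), avail)
    ds.validate()
    return ds


def write_availability_csv(dataset: SurveyDataset, path: str | Path) -> None:
    """Explicit availability table: ``state_id, year, question_id, asked``."""
    rows = []
    for (state, year) in sorted(dataset.availability):
        asked = dataset.availability[(state, year)]
        for q in dataset.catalog.question_ids:
            rows.append((state, year, q, int(q in asked)))
    pd.DataFrame(rows, columns=["state_id", "year", "question_id", "asked"]).to_csv(
        path, index=False
    )


def read_availability_csv(path: str | Path) -> dict[tuple[str, int], frozenset[str]]:
    df = pd.read_csv(path, dtype={"state_id": str})
    out: dict[tuple[str, int], set[str]] = {}
    for row in df.itertuples(index=False):
        cell = (str(row.state_id), int(row.year))
        out.setdefault(cell, set())
        if int(row.asked):
            out[cell].add(str(row.question_id))
    return {k: frozenset(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

# Between-state logit-normal parameters solved so that the induced prevalence
# distribution has mean 0.09375 and SD 0.01228 (the identity outcome's
# published per-100k moments).  See calibrate_logit_prevalence.
DEFAULT_LOGIT_MEAN = -2.277127858829011
DEFAULT_LOGIT_SD = 0.14430122651690291

# P(contact | identity) and P(contact | no identity): chosen so the implied
# contact prevalence q2 + p*(q1-q2) has mean 0.07079 and sits strictly below
# the identity prevalence in every state.
DEFAULT_CONTACT_GIVEN_LGB = 0.75
DEFAULT_CONTACT_GIVEN_NOT = 0.0005268965517241442


def calibrate_logit_prevalence(mean_prev: float, sd_prev: float) -> tuple[float, float]:
    """Solve logit-normal (mu, sigma) so state prevalences have the given moments.

    The state prevalence is ``expit(mu + sigma*Z)`` with standard-normal ``Z``;
    moments are matched by Gauss-Hermite quadrature and a two-dimensional root
    solve.
    """
    nodes, wts = np.polynomial.hermite_e.hermegauss(80)
    wts = wts / math.sqrt(2 * math.pi)

    def resid(x):
        p = special.expit(x[0] + x[1] * nodes)
        m = float(np.sum(wts * p))
        s = float(np.sqrt(np.sum(wts * (p - m) ** 2)))
        return [m - mean_prev, s - sd_prev]

    mu0 = float(special.logit(mean_prev))
    sig0 = sd_prev / (mean_prev * (1 - mean_prev))
    sol = optimize.fsolve(resid, [mu0, sig0])
    return float(sol[0]), float(sol[1])


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic multi-state survey generator.

    The defaults are calibrated to the published structure of 2013-2017 state
    YRBS data: ~40 states, a 79-item questionnaire (3 focal + 76 other
    questions), identity prevalence mean 9,375 per 100k with between-state SD
    1,228, contact prevalence mean 7,079 per 100k and everywhere below the
    identity prevalence, log-normal survey weights, MCAR item missingness, and
    uniform question-level omission.

    ``signal_strength`` scales the covariate->outcome link; at 0 every
    question is generated independently of the outcomes, while at the default
    1.0 the informative questions carry (in expectation) the full
    between-state prevalence gradient, so state differences are compositional
    rather than intercept shifts.  ``individual_logit_sd`` sets how strongly
    the risk score spreads individual outcome probabilities (within-state
    predictability), independently of the between-state calibration.
    ``interaction_flag`` switches the link from additive main effects to
    pairwise-interaction structure: informative question *pairs* whose
    within-pair response correlation tracks the state climate, a signal that
    leaves every question's marginal distribution identical across states —
    invisible to additive models but learnable by trees.
    """

    n_states: int = 40
    respondents_per_state: tuple[int, int] = (500, 1500)
    n_questions: int = 76  # non-focal questions; the catalog adds 3 focal items
    n_signal_questions: int = 4
    years: tuple[int, ...] = (2013, 2015, 2017)
    year_probs: tuple[float, ...] = (0.3, 0.6, 0.85)
    outcome1_logit_mean: float = DEFAULT_LOGIT_MEAN
    outcome1_logit_sd: float = DEFAULT_LOGIT_SD
    contact_given_lgb: float = DEFAULT_CONTACT_GIVEN_LGB
    contact_given_not: float = DEFAULT_CONTACT_GIVEN_NOT
    signal_strength: float = 1.0
    interaction_flag: bool = True
    item_missing_rate: float = 0.03
    question_omission_rate: float = 0.10
    weight_dispersion: float = 0.6
    states_without_identity: tuple[str, ...] = ()
    states_without_contact: tuple[str, ...] = ()
    seed: int = 0
    # latent-structure constants; exposed for completeness, rarely changed
    individual_latent_sd: float = 0.75
    individual_logit_sd: float = 1.5
    pair_corr_base: float = 0.3

    def validate(self) -> None:
        if self.n_states < 1:
            raise SurveyValidationError("n_states must be positive")
        lo, hi = self.respondents_per_state
        if lo < 1 or hi < lo:
            raise SurveyValidationError("respondents_per_state must be a positive range")
        if self.n_questions < 1 or not (0 <= self.n_signal_questions <= self.n_questions):
            raise SurveyValidationError("need 0 <= n_signal_questions <= n_questions >= 1")
        for p in (*self.year_probs, self.contact_given_lgb, self.contact_given_not):
            if not 0 <= p <= 1:
                raise SurveyValidationError("probabilities must lie in [0, 1]")
        for r in (self.item_missing_rate, self.question_omission_rate):
            if not 0 <= r < 1:
                raise SurveyValidationError("rates must lie in [0, 1)")
        if self.signal_strength < 0:
            raise SurveyValidationError("signal_strength must be >= 0")
        if len(self.years) != len(self.year_probs):
            raise SurveyValidationError("years and year_probs must have equal length")
        if self.weight_dispersion < 0:
            raise SurveyValidationError("weight_dispersion must be >= 0")


def _quantile_levels(v: np.ndarray, n_levels: int) -> np.ndarray:
    """Discretize standard-normal scores into 1..n_levels by N(0,1) quantiles."""
    cuts = special.ndtri(np.arange(1, n_levels) / n_levels)
    return 1 + np.searchsorted(cuts, v, side="right").astype(np.int64)


def _level_score(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Centered, unit-variance numeric score for 1..n_levels codes."""
    centered = levels - (n_levels + 1) / 2.0
    sd = math.sqrt((n_levels**2 - 1) / 12.0)
    return centered / sd

# Attenuation factors from replacing latent normal scores by their 4-level
# quantile-bin scores: correlation of the binned score with its latent (~0.92)
# and the product-moment attenuation for a pair (~0.85); used to size the
# latent coupling so signal_strength 1.0 carries the full between-state
# gradient through the observable responses.
_SCORE_LATENT_CORR = 0.92
_PRODUCT_ATTENUATION = 0.85


def _solve_intercept(z: np.ndarray, target: float) -> float:
    """Intercept a with mean(expit(a + z)) == target, by bracketed root solve."""
    def g(a: float) -> float:
        return float(np.mean(special.expit(a + z))) - target

    lo, hi = -20.0, 20.0
    return float(optimize.brentq(g, lo, hi, xtol=1e-12))


def generate_synthetic_survey(
    config: GeneratorConfig,
) -> tuple[SurveyDataset, pd.DataFrame]:
    """Generate a synthetic multi-state survey and its ground-truth prevalences.

    Returns the dataset and a DataFrame ``state_id, true_lgb_prevalence,
    true_contact_prevalence`` holding the generator's per-state truth (the
    expected coded-outcome prevalence before item missingness).

    The generative model, per state ``s`` with latent climate ``u_s ~ N(0,1)``:

    - identity prevalence ``p_s = expit(mu + sigma * u_s)``; contact prevalence
      ``c_s = q2 + p_s (q1 - q2)`` with ``q1 < 1`` so ``c_s < p_s`` always;
    - informative questions couple to the state climate either through level
      shifts along each respondent's latent ``t_i = u_s + e_i`` (main-effect
      regime) or through a state-level within-pair response correlation
      ``r_s = r0 + r1 * u_s`` (interaction regime), and a risk score built
      from the *observed* responses enters the outcome logit, whose state
      intercept is solved so the cell's mean outcome probability equals
      ``p_s`` exactly;
    - the contact outcome is drawn conditionally on the identity outcome, and
      both are re-expressed as raw questionnaire responses;
    - weights are log-normal, normalized to mean 1 within each (state, year);
      item missingness is MCAR; non-focal questions are omitted per cell at
      ``question_omission_rate``.

    The same seed always yields a bit-identical dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_sig = config.n_signal_questions
    catalog = default_catalog(config.n_questions)
    signal_ids = [f"q{i + 1:03d}" for i in range(n_sig)]
    # informative questions always use 4 levels so the latent coupling is uniform
    questions = []
    for q in catalog.questions:
        if q.question_id in signal_ids:
            questions.append(Question(q.question_id, (1, 2, 3, 4)))
        else:
            questions.append(q)
    catalog = QuestionCatalog(tuple(questions))
    noise_ids = [q.question_id for q in catalog.questions
                 if not q.is_focal and q.question_id not in signal_ids]

    # fixed response distributions for uninformative questions
    noise_probs = {
        q: rng.dirichlet(np.full(len(catalog[q].levels), 1.2)) for q in noise_ids
    }

    pairs = [(signal_ids[2 * i], signal_ids[2 * i + 1]) for i in range(n_sig // 2)]
    unpaired = signal_ids[2 * len(pairs):]

    # Risk-link calibration.  The observable risk score f (a mean of pair
    # products or of level scores) is scaled by gamma_eff so that it spreads
    # individual outcome logits by ~individual_logit_sd; the latent coupling
    # (r1 for the interaction regime, main_c for main effects) is then sized
    # so signal_strength=1 routes the full between-state gradient
    # (outcome1_logit_sd) through the responses, compositionally.
    s_e = config.individual_latent_sd
    r0 = config.pair_corr_base
    if config.interaction_flag and pairs:
        sd_f = math.sqrt((1.0 + r0 * r0) / len(pairs))
    else:
        sd_f = math.sqrt(1.0 / len(signal_ids)) if signal_ids else 1.0
    gamma_eff = config.signal_strength * config.individual_logit_sd / sd_f
    gradient_share = min(config.signal_strength, 1.0)
    r1, main_c = 0.0, 0.0
    if gamma_eff > 0:
        if config.interaction_flag and pairs:
            r1 = gradient_share * config.outcome1_logit_sd / (gamma_eff * _PRODUCT_ATTENUATION)
        else:
            amp = gradient_share * config.outcome1_logit_sd / (gamma_eff * _SCORE_LATENT_CORR)
            # undo the unit-variance normalization of the response latent
            main_c = amp / math.sqrt(max(1.0 - amp * amp * (1 + s_e * s_e), 0.25))

    states = [f"S{i + 1:02d}" for i in range(config.n_states)]
    u = rng.normal(size=config.n_states)
    p_state = special.expit(config.outcome1_logit_mean + config.outcome1_logit_sd * u)
    q1, q2 = config.contact_given_lgb, config.contact_given_not
    c_state = q2 + p_state * (q1 - q2)

    truth = pd.DataFrame(
        {
            "state_id": states,
            "true_lgb_prevalence": p_state,
            "true_contact_prevalence": c_state,
        }
    )

    frames: list[pd.DataFrame] = []
    availability: dict[tuple[str, int], frozenset[str]] = {}
    target_year = max(config.years)

    for si, state in enumerate(states):
        include = rng.random(len(config.years)) < np.asarray(config.year_probs)
        if not include.any():
            include[rng.integers(len(config.years))] = True
        state_years = [y for y, inc in zip(config.years, include) if inc]

        # per-cell question omission (uniform over non-focal questions)
        for year in state_years:
            n = int(rng.integers(config.respondents_per_state[0],
                                 config.respondents_per_state[1] + 1))
            e = rng.normal(scale=s_e, size=n)
            t = u[si] + e

            responses: dict[str, np.ndarray] = {}
            score: dict[str, np.ndarray] = {}
            if config.interaction_flag:
                r = float(np.clip(r0 + r1 * u[si], 0.02, 0.98))
                for a_id, b_id in pairs:
                    zeta = rng.normal(size=n)
                    va = np.sqrt(r) * zeta + np.sqrt(1 - r) * rng.normal(size=n)
                    vb = np.sqrt(r) * zeta + np.sqrt(1 - r) * rng.normal(size=n)
                    responses[a_id] = _quantile_levels(va, 4)
                    responses[b_id] = _quantile_levels(vb, 4)
                for qid in unpaired:
                    responses[qid] = _quantile_levels(rng.normal(size=n), 4)
            else:
                norm = math.sqrt(main_c * main_c * (1 + s_e * s_e) + 1.0)
                for qid in signal_ids:
                    v = (main_c * t + rng.normal(size=n)) / norm
                    responses[qid] = _quantile_levels(v, 4)
            for qid in signal_ids:
                score[qid] = _level_score(responses[qid], 4)

            if config.interaction_flag and pairs:
                f = np.mean([score[a] * score[b] for a, b in pairs], axis=0)
            else:
                f = np.mean([score[qid] for qid in signal_ids], axis=0) if signal_ids else np.zeros(n)

            z = gamma_eff * f
            a = _solve_intercept(z, float(p_state[si]))
            lgb = rng.random(n) < special.expit(a + z)
            contact = np.where(lgb, rng.random(n) < q1, rng.random(n) < q2)

            # express outcomes as raw questionnaire responses
            identity_resp = np.where(
                lgb,
                np.where(rng.random(n) < 0.35, IDENTITY_GAY_LESBIAN, IDENTITY_BISEXUAL),
                np.where(rng.random(n) < 0.05, IDENTITY_NOT_SURE, IDENTITY_HETEROSEXUAL),
            )
            sex = np.where(rng.random(n) < 0.5, SEX_FEMALE, SEX_MALE)
            same_sex_only = np.where(sex == SEX_MALE, CONTACT_MALES, CONTACT_FEMALES)
            opposite_only = np.where(sex == SEX_MALE, CONTACT_FEMALES, CONTACT_MALES)
            contact_resp = np.where(
                contact,
                np.where(rng.random(n) < 0.5, CONTACT_BOTH, same_sex_only),
                np.where(rng.random(n) < 0.55, CONTACT_NEVER, opposite_only),
            )
            responses["sex"] = sex
            responses["identity"] = identity_resp
            responses["contact"] = contact_resp
            for qid in noise_ids:
                levels = np.asarray(catalog[qid].levels)
                responses[qid] = rng.choice(levels, size=n, p=noise_probs[qid])

            # availability: focal controlled by config lists, others sampled
            asked = set(catalog.question_ids)
            for qid in list(asked):
                if not catalog[qid].is_focal and rng.random() < config.question_omission_rate:
                    asked.discard(qid)
            if state in config.states_without_identity:
                asked.discard("identity")
            if state in config.states_without_contact:
                asked.discard("contact")

            w = rng.lognormal(mean=0.0, sigma=config.weight_dispersion, size=n)
            w = w / w.mean()

            frame = pd.DataFrame({"state_id": state, "year": year, "weight": w})
            for qid in catalog.question_ids:
                col = pd.array(responses[qid], dtype="Int64")
                if qid not in asked:
                    col = pd.array([pd.NA] * n, dtype="Int64")
                elif config.item_missing_rate > 0:
                    mask = rng.random(n) < config.item_missing_rate
                    col[mask] = pd.NA
                frame[qid] = col
            frames.append(frame)
            availability[(state, year)] = frozenset(asked)

    data = pd.concat(frames, ignore_index=True)
    dataset = SurveyDataset(catalog, data, availability)
    return dataset, truth


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def _fmt_median_range(values: Sequence[int]) -> str:
    if not values:
        return "-"
    med = int(round(float(np.median(values))))
    return f"{med} [{min(values)}, {max(values)}]"


def summarize_dataset(dataset: SurveyDataset, outcomes) -> pd.DataFrame:
    """Dataset summary in the layout of a multi-state survey data table.

    For each focal outcome the states are split into an "available" stratum
    (the outcome question was asked in at least one of the state's surveys;
    these provide training data) and an "unavailable" stratum (prediction
    targets).  Reported statistics: respondent counts, state counts overall
    and per year, unique years per state (mean [min, max]), questions per
    state (median [min, max]), and the weighted observed outcome proportion
    across available states, per 100k (mean (SD)).

    ``outcomes`` is the :class:`~yrbsprev.outcome_coding.OutcomeTable`
    computed on this dataset.
    """
    from .state_estimation import weighted_state_proportion  # local import, no cycle

    stats_rows = [
        "n_respondents",
        "n_states",
        *[f"n_states_{y}" for y in dataset.years],
        "unique_years_per_state",
        "questions_per_state",
        "observed_proportion_per_100k",
    ]
    columns = pd.MultiIndex.from_product(
        [["lgb_identity", "same_sex_contact"], ["available", "unavailable"]]
    )
    out = pd.DataFrame(index=stats_rows, columns=columns, dtype=object)

    for outcome_name, avail_key in (
        ("lgb_identity", "identity_available"),
        ("same_sex_contact", "contact_available"),
    ):
        state_available = {}
        for state in dataset.states:
            flags = [
                outcomes.availability[(state, y)][avail_key]
                for y in dataset.state_years(state)
            ]
            state_available[state] = any(flags)
        for stratum in ("available", "unavailable"):
            states = [s for s, a in state_available.items() if a == (stratum == "available")]
            sub = dataset.data[dataset.data["state_id"].isin(states)]
            out.loc["n_respondents", (outcome_name, stratum)] = int(len(sub))
            out.loc["n_states", (outcome_name, stratum)] = len(states)
            for y in dataset.years:
                n_y = sum(1 for s in states if y in dataset.state_years(s))
                out.loc[f"n_states_{y}", (outcome_name, stratum)] = n_y
            years_per_state = [len(dataset.state_years(s)) for s in states]
            if years_per_state:
                out.loc["unique_years_per_state", (outcome_name, stratum)] = (
                    f"{np.mean(years_per_state):.1f} "
                    f"[{min(years_per_state)}, {max(years_per_state)}]"
                )
            else:
                out.loc["unique_years_per_state", (outcome_name, stratum)] = "-"
            q_counts = [
                len(frozenset().union(*[dataset.availability[(s, y)] for y in dataset.state_years(s)]))
                for s in states
            ]
            out.loc["questions_per_state", (outcome_name, stratum)] = _fmt_median_range(q_counts)

            if stratum == "available":
                props = []
                for s in states:
                    years = [
                        y for y in dataset.state_years(s)
                        if outcomes.availability[(s, y)][avail_key]
                    ]
                    if not years:
                        continue
                    y = max(years)
                    cell_mask = (dataset.data["state_id"] == s) & (dataset.data["year"] == y)
                    w = dataset.data.loc[cell_mask, "weight"].to_numpy()
                    vals = outcomes.table.loc[cell_mask.to_numpy(), outcome_name].to_numpy(float)
                    props.append(weighted_state_proportion(vals, w))
                if props:
                    out.loc["observed_proportion_per_100k", (outcome_name, stratum)] = (
                        f"{np.mean(props) * 1e5:,.0f} ({np.std(props, ddof=1) * 1e5:,.0f})"
                        if len(props) > 1
                        else f"{np.mean(props) * 1e5:,.0f} (-)"
                    )
                else:
                    out.loc["observed_proportion_per_100k", (outcome_name, stratum)] = "-"
            else:
                out.loc["observed_proportion_per_100k", (outcome_name, stratum)] = "-"
    return out
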