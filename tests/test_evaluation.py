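"""Task assignment, LOO integrity, ICC oracle, metrics, selection, sweep."""

import numpy as np
import pandas as pd
import pytest

from yrbsprev import (
    GeneratorConfig,
    ModelSpec,
    attach_outcomes,
    evaluate_models,
    generate_synthetic_survey,
    icc,
    interval_coverage,
    loo_state_cv,
    mean_absolute_error_pp,
    ordering_check,
    predict_unobserved_states,
    predictor_sweep,
    select_best_model,
)
from yrbsprev.evaluation import EvaluationError, assign_tasks

FAST_RF = {"max_depth": [6], "n_trees": [50], "max_features_per_split": ["sqrt"]}


class TestAssignTasks:
    def test_state_with_both_years_everything_asked(self, multi_year_dataset):
        out = attach_outcomes(multi_year_dataset)
        tasks = assign_tasks(multi_year_dataset, out, "A", "lgb_identity")
        assert tasks == {
            "same_year_with_other",
            "same_year_without_other",
            "prev_year_without_other",
        }

    def test_missing_other_focal_drops_task1(self, multi_year_dataset):
        out = attach_outcomes(multi_year_dataset)
        tasks = assign_tasks(multi_year_dataset, out, "B", "lgb_identity")
        assert tasks == {"same_year_without_other"}

    def test_only_previous_year_not_evaluable(self, multi_year_dataset):
        # C has only 2015 data: its 2017 observed proportion does not exist,
        # so it cannot be scored in evaluate mode ...
        out = attach_outcomes(multi_year_dataset)
        assert assign_tasks(multi_year_dataset, out, "C", "lgb_identity") == set()
        # ... but it is a previous-year prediction target in predict mode
        assert assign_tasks(
            multi_year_dataset, out, "C", "lgb_identity", mode="predict"
        ) == {"prev_year_without_other"}

    def test_unobserved_outcome_is_prediction_target(self, multi_year_dataset):
        out = attach_outcomes(multi_year_dataset)
        assert assign_tasks(multi_year_dataset, out, "D", "lgb_identity") == set()
        pred = assign_tasks(multi_year_dataset, out, "D", "lgb_identity", mode="predict")
        assert pred == {"same_year_without_other", "same_year_with_other"}

    def test_errors(self, multi_year_dataset):
        out = attach_outcomes(multi_year_dataset)
        with pytest.raises(EvaluationError):
            assign_tasks(multi_year_dataset, out, "A", "lgb_identity", mode="nope")
        with pytest.raises(EvaluationError):
            assign_tasks(multi_year_dataset, out, "A", "unknown_outcome")


class TestIccOracle:
    def _pingouin_icc2(self, x, y):
        import pingouin as pg

        n = len(x)
        df = pd.DataFrame(
            {
                "targets": list(range(n)) * 2,
                "raters": ["a"] * n + ["b"] * n,
                "scores": list(x) + list(y),
            }
        )
        res = pg.intraclass_corr(
            df, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
        row = res.loc["ICC2"] if "ICC2" in res.index else res.loc["ICC(A,1)"]
        return float(row["ICC"]), float(row["pval"])

    def test_matches_pingouin_on_5_pair_fixture(self):
        x = [0.08, 0.09, 0.11, 0.10, 0.12]
        y = [0.085, 0.095, 0.105, 0.11, 0.118]
        v, p = icc(x, y)
        ov, op = self._pingouin_icc2(x, y)
        assert v == pytest.approx(ov, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)

    def test_matches_pingouin_on_random_10_pair_fixtures(self, rng):
        for _ in range(5):
            x = rng.normal(0.1, 0.02, size=10)
            y = x + rng.normal(0, 0.01, size=10)
            v, p = icc(x, y)
            ov, op = self._pingouin_icc2(x, y)
            assert v == pytest.approx(ov, abs=1e-10)
            assert p == pytest.approx(op, abs=1e-10)

    def test_perfect_agreement(self):
        x = [0.1, 0.2, 0.3, 0.4]
        v, p = icc(x, x)
        assert v == pytest.approx(1.0, abs=1e-12)
        assert p == 0.0

    def test_constant_shift_penalized_below_correlation(self):
        x = np.array([0.10, 0.12, 0.14, 0.16, 0.18])
        y = x + 0.05  # correlation 1, agreement poor
        v, _ = icc(x, y)
        assert v < 0.9
        assert v < np.corrcoef(x, y)[0, 1]

    def test_independent_vectors_near_zero(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        v, p = icc(x, y)
        assert abs(v) < 0.15
        assert p > 0.01

    def test_errors(self):
        with pytest.raises(EvaluationError):
            icc([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(EvaluationError):
            icc([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])


class TestSimpleMetrics:
    def test_coverage_closed_boundaries(self):
        frame = pd.DataFrame(
            {
                "observed": [0.10, 0.20, 0.30, 0.40],
                "lower": [0.10, 0.25, 0.25, 0.0],
                "upper": [0.15, 0.30, 0.30, 0.39],
            }
        )
        # on lower bound: covered; below: not; on upper bound: covered; above: not
        assert interval_coverage(frame) == pytest.approx(0.5)

    def test_mae_pp(self):
        frame = pd.DataFrame({"point": [0.10, 0.09], "observed": [0.09, 0.10]})
        assert mean_absolute_error_pp(frame) == pytest.approx(1.0)
        perfect = pd.DataFrame({"point": [0.1], "observed": [0.1]})
        assert mean_absolute_error_pp(perfect) == 0.0

    def test_empty_errors(self):
        empty = pd.DataFrame(columns=["observed", "lower", "upper", "point"])
        with pytest.raises(EvaluationError):
            interval_coverage(empty)
        with pytest.raises(EvaluationError):
            mean_absolute_error_pp(empty)


class TestSelection:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["outcome", "task", "family", "icc"]
        )

    def test_argmax_on_primary_task(self):
        frame = self._frame(
            [
                ("lgb_identity", "same_year_with_other", "ols", 0.5),
                ("lgb_identity", "same_year_with_other", "gbrt", 0.8),
                ("lgb_identity", "same_year_without_other", "ols", 0.9),
            ]
        )
        assert select_best_model(frame) == {"lgb_identity": "gbrt"}

    def test_exact_tie_prefers_random_forest(self):
        frame = self._frame(
            [
                ("lgb_identity", "same_year_with_other", "gbrt", 0.81),
                ("lgb_identity", "same_year_with_other", "random_forest", 0.81),
            ]
        )
        assert select_best_model(frame) == {"lgb_identity": "random_forest"}

    def test_fallback_task_when_primary_absent(self):
        frame = self._frame(
            [
                ("same_sex_contact", "same_year_without_other", "ols", 0.4),
                ("same_sex_contact", "same_year_without_other", "logistic", 0.6),
            ]
        )
        assert select_best_model(frame) == {"same_sex_contact": "logistic"}

    def test_empty_errors(self):
        with pytest.raises(EvaluationError):
            select_best_model(pd.DataFrame())


class TestOrderingCheck:
    def test_reports_and_fraction(self):
        lgb = pd.DataFrame({"state_id": ["A", "B"], "point": [0.10, 0.07]})
        ct = pd.DataFrame({"state_id": ["B", "A"], "point": [0.08, 0.07]})
        report, frac = ordering_check(lgb, ct)
        assert report.set_index("state_id")["lgb_greater"].to_dict() == {
            "A": True, "B": False,
        }
        assert frac == pytest.approx(0.5)

    def test_equality_is_not_greater(self):
        lgb = pd.DataFrame({"state_id": ["A"], "point": [0.1]})
        ct = pd.DataFrame({"state_id": ["A"], "point": [0.1]})
        _, frac = ordering_check(lgb, ct)
        assert frac == 0.0

    def test_mismatched_states_error(self):
        lgb = pd.DataFrame({"state_id": ["A"], "point": [0.1]})
        ct = pd.DataFrame({"state_id": ["B"], "point": [0.1]})
        with pytest.raises(EvaluationError):
            ordering_check(lgb, ct)


@pytest.fixture(scope="module")
def small_survey():
    cfg = GeneratorConfig(
        n_states=6, respondents_per_state=(120, 160), n_questions=8,
        n_signal_questions=4, seed=31, question_omission_rate=0.0,
    )
    ds, truth = generate_synthetic_survey(cfg)
    return ds, attach_outcomes(ds), truth


class TestLooIntegrity:
    def test_loo_never_trains_on_held_out_state(self, small_survey):
        ds, out, _ = small_survey
        spec = ModelSpec("random_forest", grid=FAST_RF, seed=2)
        res = loo_state_cv(ds, out, spec, "same_year_without_other", "lgb_identity")
        assert len(res.estimates) >= 3
        for est in res.estimates:
            diag = res.diagnostics[est.state_id]
            assert est.state_id not in diag["train_states"]
            assert est.state_id not in diag["residual_pool_states"]
            # every other evaluated state contributes to the pool
            others = {e.state_id for e in res.estimates} - {est.state_id}
            assert set(diag["residual_pool_states"]) == others

    def test_residual_convention_and_frame(self, small_survey):
        ds, out, _ = small_survey
        spec = ModelSpec("ols", seed=2)
        res = loo_state_cv(ds, out, spec, "same_year_without_other", "lgb_identity")
        fr = res.to_frame()
        for est in res.estimates:
            s = est.state_id
            assert res.residuals[s] == pytest.approx(
                res.observed[s] - est.point, abs=1e-12
            )
            assert est.interval_lower <= est.point <= est.interval_upper or (
                est.interval_lower >= 0 and est.interval_upper <= 1
            )
        assert set(fr.columns) >= {
            "state_id", "point", "lower", "upper", "observed", "task", "model_family",
        }

    def test_task1_uses_other_outcome_column(self, small_survey):
        ds, out, _ = small_survey
        spec = ModelSpec("ols", include_other_outcome=True, seed=2)
        res = loo_state_cv(ds, out, spec, "same_year_with_other", "lgb_identity")
        assert len(res.estimates) >= 3

    def test_too_few_states_error(self, multi_year_dataset):
        out = attach_outcomes(multi_year_dataset)
        with pytest.raises(EvaluationError):
            loo_state_cv(
                multi_year_dataset, out, ModelSpec("ols"),
                "same_year_without_other", "lgb_identity",
            )

    def test_unknown_task_error(self, small_survey):
        ds, out, _ = small_survey
        with pytest.raises(EvaluationError):
            loo_state_cv(ds, out, ModelSpec("ols"), "next_year", "lgb_identity")


class TestEvaluateModelsDriver:
    def test_report_shape_and_selection(self, small_survey):
        ds, out, _ = small_survey
        report, results = evaluate_models(
            ds, out,
            families=["ols", "random_forest"],
            tasks=["same_year_without_other"],
            outcome_names=["lgb_identity"],
            grids={"random_forest": FAST_RF},
            seed=3,
        )
        assert set(report.frame["family"]) == {"ols", "random_forest"}
        assert (report.frame["n_states"] >= 3).all()
        assert report.frame["icc"].between(-1, 1).all()
        assert report.frame["coverage"].between(0, 1).all()
        assert report.selected["lgb_identity"] in {"ols", "random_forest"}
        assert set(results) == {
            ("lgb_identity", "same_year_without_other", "ols"),
            ("lgb_identity", "same_year_without_other", "random_forest"),
        }

    def test_infeasible_task_skipped(self, small_survey):
        ds, out, _ = small_survey
        # drop all non-target years to make the previous-year task infeasible
        target = max(ds.years)
        mask = (ds.data["year"] == target).to_numpy()
        ds2, out2 = ds.select_rows(mask), out.select_rows(mask)
        report, results = evaluate_models(
            ds2, out2, families=["ols"],
            tasks=["same_year_without_other", "prev_year_without_other"],
            outcome_names=["lgb_identity"], seed=3,
        )
        assert set(report.frame["task"]) == {"same_year_without_other"}


class TestPredictUnobserved:
    def test_observed_predicted_and_sources(self):
        cfg = GeneratorConfig(
            n_states=7, respondents_per_state=(100, 140), n_questions=8,
            n_signal_questions=4, seed=77, question_omission_rate=0.0,
            states_without_identity=("S02",),
        )
        ds, _ = generate_synthetic_survey(cfg)
        out = attach_outcomes(ds)
        frame = predict_unobserved_states(
            ds, out, ModelSpec("ols", seed=1), "lgb_identity"
        )
        assert set(frame["state_id"]) == set(ds.states)
        by_state = frame.set_index("state_id")
        target = max(ds.years)
        for s in ds.states:
            has_obs = target in ds.state_years(s) and out.available(
                s, target, "lgb_identity"
            )
            assert by_state.loc[s, "source"] == ("observed" if has_obs else "predicted")
        assert by_state.loc["S02", "source"] == "predicted"
        pred = by_state.loc["S02"]
        assert 0 <= pred["lower"] <= pred["point"] <= pred["upper"] <= 1


class TestPredictorSweep:
    def test_zero_predictors_equalizes_families(self, small_survey):
        ds, out, _ = small_survey
        specs = [
            ModelSpec("ols", seed=4),
            ModelSpec("random_forest", grid=FAST_RF, seed=4),
        ]
        table = predictor_sweep(ds, out, specs, [0], seed=4, n_folds=3)
        losses = table["cv_loss"].to_numpy()
        assert np.allclose(losses, losses[0], atol=1e-12)

    def test_loss_decreases_with_signal_questions(self, small_survey):
        ds, out, _ = small_survey
        specs = [ModelSpec("logistic", seed=4)]
        table = predictor_sweep(ds, out, specs, [0, 8], seed=4, n_folds=3)
        loss0 = table.loc[table["n_predictors"] == 0, "cv_loss"].item()
        loss8 = table.loc[table["n_predictors"] == 8, "cv_loss"].item()
        assert loss8 <= loss0 + 1e-4

    def test_count_exceeding_questions_errors(self, small_survey):
        ds, out, _ = small_survey
        with pytest.raises(EvaluationError):
            predictor_sweep(ds, out, [ModelSpec("ols")], [99], seed=0)
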