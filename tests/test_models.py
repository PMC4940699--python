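import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

from ckdval import models as M
from ckdval.models import (
    DevelopmentSummary,
    ModelConfigError,
    apply_score,
    estimate_intercept,
    linear_predictor,
    load_model_spec,
    mean_lp_from_individuals,
    mean_lp_from_summary,
    predict_cox,
    predict_logistic,
)
from ckdval.pipeline import packaged_model_paths
from ckdval.synthetic import generate_from_model


def logistic_spec(**overrides):
    doc = {
        "name": "toy",
        "family": "logistic",
        "horizon_years": 5,
        "intercept": 0.0,
        "terms": [
            {"predictor": "x1", "transform": "identity", "beta": 1.0},
            {"predictor": "x2", "transform": "identity", "beta": 0.25},
        ],
    }
    doc.update(overrides)
    return load_model_spec(doc)


class TestLoader:
    def test_logistic_without_intercept_but_with_summary_loads(self):
        spec = logistic_spec(
            intercept=None,
            development_summary={"prevalence": 0.1, "summaries": {"x1": 0.5, "x2": 2.0}},
        )
        assert spec.intercept is None and spec.development_summary is not None

    def test_logistic_without_intercept_or_summary_rejected(self):
        with pytest.raises(ModelConfigError):
            logistic_spec(intercept=None)

    def test_cox_without_baseline_survival_rejected(self):
        with pytest.raises(ModelConfigError, match="baseline_survival"):
            load_model_spec(
                {"name": "c", "family": "cox", "horizon_years": 5,
                 "terms": [{"predictor": "x", "beta": 1.0}]}
            )

    def test_unknown_transform_rejected(self):
        with pytest.raises(ModelConfigError, match="transform"):
            logistic_spec(terms=[{"predictor": "x", "transform": "cubist", "beta": 1.0}])

    def test_dropped_term_is_tracked(self):
        spec = logistic_spec(
            terms=[
                {"predictor": "x1", "beta": 1.0},
                {"predictor": "proteinuria", "beta": 0.9, "dropped": True},
            ]
        )
        assert [t.predictor for t in spec.dropped_terms] == ["proteinuria"]

    def test_score_with_non_integer_points_rejected(self):
        with pytest.raises(ModelConfigError, match="integer"):
            load_model_spec(
                {"name": "s", "family": "score", "horizon_years": 5,
                 "terms": [{"predictor": "x", "points": 1.5}]}
            )

    def test_all_packaged_configs_load(self):
        paths = packaged_model_paths()
        assert len(paths) == 12
        for path in paths:
            spec = load_model_spec(path)
            assert spec.family in ("logistic", "cox", "score")


class TestLinearPredictor:
    def test_zero_covariates_give_zero(self):
        spec = logistic_spec()
        assert linear_predictor(spec, {"x1": 0.0, "x2": 0.0}) == 0.0

    def test_hand_arithmetic(self):
        spec = logistic_spec()
        assert linear_predictor(spec, {"x1": 0.5, "x2": 2.0}) == pytest.approx(1.0)

    def test_dropped_term_contributes_nothing(self):
        spec = logistic_spec(
            terms=[
                {"predictor": "x1", "beta": 1.0},
                {"predictor": "x2", "beta": 0.25},
                {"predictor": "x3", "beta": 5.0, "dropped": True},
            ]
        )
        assert linear_predictor(spec, {"x1": 0.5, "x2": 2.0}) == pytest.approx(1.0)

    def test_missing_covariate_names_predictor(self):
        spec = logistic_spec()
        with pytest.raises(ValueError, match="x2"):
            linear_predictor(spec, {"x1": 0.5})

    def test_missing_cell_names_patient(self):
        spec = logistic_spec()
        frame = pd.DataFrame({"x1": [0.1, np.nan], "x2": [1.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            linear_predictor(spec, frame)

    def test_transform_vocabulary(self):
        spec = load_model_spec(
            {
                "name": "t", "family": "logistic", "horizon_years": 5, "intercept": 0.0,
                "terms": [
                    {"predictor": "a", "transform": "centered", "center": 10.0, "beta": 1.0},
                    {"predictor": "b", "transform": "log", "beta": 1.0},
                    {"predictor": "c", "transform": "fp", "power": 2, "scale": 10.0, "beta": 1.0},
                    {"predictor": "d", "transform": "ge", "threshold": 5, "beta": 1.0},
                    {"predictor": "e", "transform": "indicator", "level": 2, "beta": 1.0},
                ],
            }
        )
        cov = {"a": 12.0, "b": math.e, "c": 30.0, "d": 5.0, "e": 2}
        # 2 + 1 + 9 + 1 + 1
        assert linear_predictor(spec, cov) == pytest.approx(14.0)


class TestRiskPredictions:
    def test_logistic_symmetry(self):
        spec = logistic_spec()
        assert predict_logistic(spec, {"x1": 0.0, "x2": 0.0}) == pytest.approx(0.5)

    def test_logistic_known_intercept(self):
        spec = logistic_spec(intercept=math.log(1 / 9))
        assert predict_logistic(spec, {"x1": 0.0, "x2": 0.0}) == pytest.approx(0.1)

    def test_logistic_monotone_in_lp(self):
        spec = logistic_spec()
        grid = [predict_logistic(spec, {"x1": v, "x2": 0.0}) for v in np.linspace(-4, 4, 21)]
        assert np.all(np.diff(grid) > 0)

    def test_logistic_without_intercept_directs_to_estimate(self):
        spec = logistic_spec(
            intercept=None,
            development_summary={"prevalence": 0.1, "summaries": {"x1": 0.0, "x2": 0.0}},
        )
        with pytest.raises(ModelConfigError, match="estimate_intercept"):
            predict_logistic(spec, {"x1": 0.0, "x2": 0.0})

    def cox_spec(self, s0=0.95, lp_bar=0.0):
        return load_model_spec(
            {"name": "cx", "family": "cox", "horizon_years": 5,
             "baseline_survival": s0, "lp_bar": lp_bar,
             "terms": [{"predictor": "x", "beta": 1.0}]}
        )

    def test_cox_baseline_patient(self):
        assert predict_cox(self.cox_spec(), {"x": 0.0}) == pytest.approx(0.05)

    def test_cox_doubled_hazard(self):
        assert predict_cox(self.cox_spec(), {"x": math.log(2)}) == pytest.approx(0.0975)

    def test_cox_certain_survival(self):
        assert predict_cox(self.cox_spec(s0=1.0), {"x": 3.0}) == 0.0

    def test_cox_centering_constant_shifts_risk(self):
        centered = self.cox_spec(lp_bar=1.0)
        plain = self.cox_spec()
        assert predict_cox(centered, {"x": 1.0}) == pytest.approx(
            predict_cox(plain, {"x": 0.0})
        )


class TestIntercept:
    def test_no_terms_even_prevalence(self):
        spec = load_model_spec(
            {"name": "e", "family": "logistic", "horizon_years": 5, "terms": [],
             "development_summary": {"prevalence": 0.5, "summaries": {}}}
        )
        assert estimate_intercept(spec) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        spec = logistic_spec(
            intercept=None,
            development_summary={"prevalence": 0.1, "summaries": {"x1": 0.5, "x2": 2.0}},
        )
        assert estimate_intercept(spec) == pytest.approx(math.log(1 / 9) - 1.0, abs=1e-9)

    def test_round_trip_reproduces_prevalence(self):
        spec = logistic_spec(
            intercept=None,
            development_summary={"prevalence": 0.1, "summaries": {"x1": 0.5, "x2": 2.0}},
        )
        filled = M.with_estimated_intercept(spec)
        risk = predict_logistic(filled, {"x1": 0.5, "x2": 2.0})
        assert risk == pytest.approx(0.1, abs=1e-12)

    def test_missing_summary_named(self):
        spec = logistic_spec(
            intercept=None,
            development_summary={"prevalence": 0.1, "summaries": {"x1": 0.5}},
        )
        with pytest.raises(ModelConfigError, match="x2"):
            estimate_intercept(spec)


class TestScore:
    score = load_model_spec(
        {"name": "sc", "family": "score", "horizon_years": 5,
         "terms": [
             {"predictor": "age", "transform": "ge", "threshold": 60, "points": 3},
             {"predictor": "diabetes", "points": 2},
         ]}
    )

    def test_no_conditions(self):
        assert apply_score(self.score, {"age": 40, "diabetes": 0}) == 0

    def test_hand_sum(self):
        assert apply_score(self.score, {"age": 65, "diabetes": 1}) == 5

    def test_monotone_in_conditions(self):
        without = apply_score(self.score, {"age": 65, "diabetes": 0})
        with_flag = apply_score(self.score, {"age": 65, "diabetes": 1})
        assert with_flag >= without


class TestMeanLinearPredictor:
    def test_summary_hand_arithmetic(self):
        spec = load_model_spec(
            {"name": "m", "family": "logistic", "horizon_years": 5, "intercept": -3.0,
             "terms": [
                 {"predictor": "b", "beta": 1.0},
                 {"predictor": "c", "beta": 0.05},
             ],
             "development_summary": {"prevalence": 0.2,
                                     "summaries": {"b": 0.2, "c": 10.0}}}
        )
        assert mean_lp_from_summary(spec) == pytest.approx(-2.3)
        assert mean_lp_from_summary(spec, include_intercept=False) == pytest.approx(0.7)

    def test_no_terms_no_intercept_is_zero(self):
        spec = load_model_spec(
            {"name": "m0", "family": "logistic", "horizon_years": 5, "intercept": -1.0,
             "terms": [],
             "development_summary": {"prevalence": 0.2, "summaries": {}}}
        )
        assert mean_lp_from_summary(spec, include_intercept=False) == 0.0

    def test_estimated_intercept_identity(self):
        # with b0 from estimate_intercept, the summary mean LP is logit(pi)
        spec = logistic_spec(
            intercept=None,
            development_summary={"prevalence": 0.1, "summaries": {"x1": 0.5, "x2": 2.0}},
        )
        filled = M.with_estimated_intercept(spec)
        assert mean_lp_from_summary(filled) == pytest.approx(math.log(1 / 9), abs=1e-12)

    def test_individual_hand_arithmetic(self):
        spec = load_model_spec(
            {"name": "mi", "family": "logistic", "horizon_years": 5, "intercept": 0.0,
             "terms": [{"predictor": "x", "beta": 1.0}]}
        )
        mean, sd = mean_lp_from_individuals(spec, pd.DataFrame({"x": [-4.0, -2.0]}))
        assert mean == pytest.approx(-3.0)
        assert sd == pytest.approx(math.sqrt(2))

    def test_identical_patients_zero_sd(self):
        spec = logistic_spec()
        frame = pd.DataFrame({"x1": [1.0] * 5, "x2": [2.0] * 5})
        _, sd = mean_lp_from_individuals(spec, frame)
        assert sd == 0.0

    def test_degenerate_cohort_matches_summary(self):
        spec = load_model_spec(
            {"name": "md", "family": "logistic", "horizon_years": 5, "intercept": -2.0,
             "terms": [{"predictor": "x", "beta": 0.7}],
             "development_summary": {"prevalence": 0.2, "summaries": {"x": 1.3}}}
        )
        frame = pd.DataFrame({"x": [1.3] * 4})
        mean, _ = mean_lp_from_individuals(spec, frame)
        assert mean == pytest.approx(mean_lp_from_summary(spec))


class TestAlgebraicInvariants:
    def test_centering_reparameterization_preserves_risk(self):
        base = load_model_spec(
            {"name": "b", "family": "logistic", "horizon_years": 5, "intercept": -1.0,
             "terms": [{"predictor": "x", "beta": 0.8}]}
        )
        # x - c with compensating intercept shift b0 + beta*c
        shifted = load_model_spec(
            {"name": "s", "family": "logistic", "horizon_years": 5,
             "intercept": -1.0 + 0.8 * 3.0,
             "terms": [{"predictor": "x", "transform": "centered", "center": 3.0,
                        "beta": 0.8}]}
        )
        for x in np.linspace(-5, 5, 11):
            assert predict_logistic(base, {"x": x}) == pytest.approx(
                predict_logistic(shifted, {"x": x}), abs=1e-12
            )

    def test_score_rank_concordant_with_parent_model(self):
        parent = load_model_spec(
            {"name": "p", "family": "logistic", "horizon_years": 5, "intercept": -4.0,
             "terms": [
                 {"predictor": "age", "beta": 0.05},
                 {"predictor": "diabetes", "beta": 0.9},
             ]}
        )
        score = load_model_spec(
            {"name": "ps", "family": "score", "horizon_years": 5,
             "terms": [
                 {"predictor": "age", "transform": "ge", "threshold": 55, "points": 2},
                 {"predictor": "diabetes", "points": 1},
             ]}
        )
        sample = generate_from_model(
            parent,
            {"age": ("normal", 50, 12), "diabetes": ("bernoulli", 0.2)},
            n=2000, seed=4,
        )
        tau, _ = kendalltau(
            np.asarray(apply_score(score, sample[["age", "diabetes"]])),
            sample["risk"].to_numpy(),
        )
        assert tau > 0.5
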