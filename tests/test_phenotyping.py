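import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ckdval.phenotyping import (
    OutcomeDefinition,
    build_cohort,
    detect_ckd_onset,
    egfr_ckdepi,
    egfr_mdrd,
    extract_predictors,
    flag_nice_risk_group,
)

from conftest import make_bundle, patient
from oracles import onset_exhaustive


class TestEgfrEquations:
    def test_mdrd_reference_values(self):
        assert egfr_mdrd(1.0, 50, female=False) == pytest.approx(79.1, abs=0.05)
        assert egfr_mdrd(2.0, 50, female=False) == pytest.approx(35.5, abs=0.05)

    def test_mdrd_female_factor_exact(self):
        male = egfr_mdrd(1.1, 62, female=False)
        female = egfr_mdrd(1.1, 62, female=True)
        assert female / male == pytest.approx(0.742, abs=1e-12)

    def test_ckdepi_reference_values(self):
        assert egfr_ckdepi(0.9, 50, female=False) == pytest.approx(99.2, abs=0.1)
        assert egfr_ckdepi(0.7, 50, female=True) == pytest.approx(101.0, abs=0.1)

    def test_ckdepi_piecewise_boundary_continuous(self):
        eps = 1e-9
        below = egfr_ckdepi(0.9 - eps, 40, female=False)
        above = egfr_ckdepi(0.9 + eps, 40, female=False)
        assert below == pytest.approx(above, abs=1e-5)

    @pytest.mark.parametrize("func", [egfr_mdrd, egfr_ckdepi])
    def test_strictly_decreasing_in_creatinine_and_age(self, func):
        cr = np.linspace(0.4, 4.0, 40)
        values = func(cr, 50, female=False)
        assert np.all(np.diff(values) < 0)
        ages = np.linspace(20, 90, 40)
        values = func(1.2, ages, female=True)
        assert np.all(np.diff(values) < 0)

    def test_nonpositive_creatinine_rejected(self):
        with pytest.raises(ValueError):
            egfr_mdrd(0.0, 50, female=False)

    def test_ckdepi_lower_than_mdrd_for_elderly(self):
        # the sensitivity analysis on the estimating equation rests on this
        assert egfr_ckdepi(1.3, 85, female=False) < egfr_mdrd(1.3, 85, female=False)


class TestOnsetDetection:
    def test_two_low_values_spanning_100_days(self):
        assert detect_ckd_onset([(0, 55), (100, 58)]) == 100

    def test_short_run_broken_by_recovery(self):
        assert detect_ckd_onset([(0, 55), (30, 55), (200, 70)]) is None

    def test_code_arm_alone(self):
        assert detect_ckd_onset([], code_dates=[50]) == 50

    def test_span_reached_at_third_measurement(self):
        assert detect_ckd_onset([(0, 55), (30, 58), (120, 59)]) == 120

    def test_intervening_recovery_resets_run(self):
        # 90+ days overall, but a >=60 value splits the run
        assert detect_ckd_onset([(0, 55), (50, 61), (100, 58)]) is None

    def test_code_earlier_than_lab_confirmation(self):
        assert detect_ckd_onset([(0, 55), (100, 58)], code_dates=[40]) == 40

    def test_single_rule_fires_on_first_low_value(self):
        definition = OutcomeDefinition(rule="single")
        assert detect_ckd_onset([(10, 59), (100, 70)], definition=definition) == 10

    def test_same_day_duplicates_use_lowest(self):
        # day 0 has 62 and 55: the 55 starts the run
        assert detect_ckd_onset([(0, 62), (0, 55), (95, 58)]) == 95

    def test_timestamps_round_trip(self):
        series = [("2010-01-01", 55.0), ("2010-06-01", 58.0)]
        onset = detect_ckd_onset(series)
        assert onset == pd.Timestamp("2010-06-01")

    @given(
        st.lists(
            st.tuples(st.integers(0, 400), st.floats(40, 80)),
            min_size=0, max_size=6,
        ),
        st.lists(st.integers(0, 400), min_size=0, max_size=2),
        st.sampled_from(["main", "single"]),
    )
    def test_matches_exhaustive_enumeration(self, pairs, code_days, rule):
        definition = OutcomeDefinition(rule=rule)
        got = detect_ckd_onset(pairs, code_days, definition)
        expected = onset_exhaustive(pairs, code_days, rule)
        assert got == expected

    def test_single_rule_dominates_main_rule(self, small_bundle):
        main = build_cohort(small_bundle, OutcomeDefinition(rule="main"))
        single = build_cohort(small_bundle, OutcomeDefinition(rule="single"))
        assert (single["event"] == "ckd").sum() >= (main["event"] == "ckd").sum()


class TestCohortSelection:
    def test_minor_excluded(self):
        bundle = make_bundle(
            patients=[patient("a", birth="1993-01-01")],
            labs=[{"id": "a", "date": "2009-06-01", "analyte": "creatinine", "value": 1.0}],
        )
        assert build_cohort(bundle).empty

    def test_no_in_window_record_excluded(self):
        bundle = make_bundle(
            patients=[patient("a", birth="1960-01-01")],
            labs=[{"id": "a", "date": "2008-06-01", "analyte": "creatinine", "value": 1.0}],
        )
        assert build_cohort(bundle).empty

    def test_prevalent_ckd_excluded(self):
        bundle = make_bundle(
            patients=[patient("a", birth="1950-01-01")],
            labs=[
                {"id": "a", "date": "2008-01-01", "analyte": "creatinine", "value": 2.0},
                {"id": "a", "date": "2008-06-01", "analyte": "creatinine", "value": 2.0},
                {"id": "a", "date": "2009-06-01", "analyte": "creatinine", "value": 1.0},
            ],
        )
        assert build_cohort(bundle).empty

    def test_pre_entry_code_marks_prevalent(self):
        bundle = make_bundle(
            patients=[patient("a", birth="1950-01-01")],
            labs=[{"id": "a", "date": "2009-06-01", "analyte": "creatinine", "value": 1.0}],
            codes=[{"id": "a", "date": "2007-01-01", "code_class": "ckd_stage_3_5"}],
        )
        assert build_cohort(bundle).empty

    def test_entry_is_first_in_window_record(self):
        bundle = make_bundle(
            patients=[patient("a", birth="1950-01-01")],
            labs=[
                {"id": "a", "date": "2009-05-10", "analyte": "creatinine", "value": 1.0},
                {"id": "a", "date": "2009-08-01", "analyte": "creatinine", "value": 1.0},
            ],
        )
        cohort = build_cohort(bundle)
        assert cohort.iloc[0]["entry_date"] == pd.Timestamp("2009-05-10")
        assert bundle.entry_start <= cohort.iloc[0]["entry_date"] <= bundle.entry_end

    def test_censoring_at_moveout_incomplete_followup(self):
        bundle = make_bundle(
            patients=[patient("a", birth="1950-01-01", moveout="2012-06-01")],
            labs=[{"id": "a", "date": "2009-06-01", "analyte": "creatinine", "value": 1.0}],
        )
        row = build_cohort(bundle).iloc[0]
        assert row["event"] == "censored"
        assert row["followup_years"] == pytest.approx(3.0, abs=0.01)
        assert not row["complete_followup"]

    def test_administrative_censoring_complete_followup(self):
        bundle = make_bundle(
            patients=[patient("a", birth="1950-01-01")],
            labs=[{"id": "a", "date": "2009-06-01", "analyte": "creatinine", "value": 1.0}],
        )
        row = build_cohort(bundle).iloc[0]
        assert row["followup_years"] > 5
        assert row["complete_followup"]

    def test_death_censors_or_counts_as_event(self):
        bundle = make_bundle(
            patients=[patient("a", birth="1930-01-01", death="2011-06-01")],
            labs=[{"id": "a", "date": "2009-06-01", "analyte": "creatinine", "value": 1.0}],
        )
        row = build_cohort(bundle).iloc[0]
        assert row["event"] == "death" and not row["complete_followup"]
        recoded = build_cohort(bundle, OutcomeDefinition(death_as_event=True)).iloc[0]
        assert recoded["event"] == "ckd" and recoded["event_within_horizon"] == 1
        assert recoded["complete_followup"]

    def test_onset_dates_never_precede_entry(self, small_bundle):
        cohort = build_cohort(small_bundle)
        with_onset = cohort.dropna(subset=["onset_date"])
        assert (with_onset["onset_date"] >= with_onset["entry_date"]).all()

    def test_empty_bundle_warns(self):
        bundle = make_bundle()
        with pytest.warns(UserWarning):
            assert build_cohort(bundle).empty


class TestPredictorExtraction:
    def base_bundle(self, labs=(), codes=(), prescriptions=()):
        rows = [{"id": "a", "date": "2009-06-01", "analyte": "creatinine", "value": 1.0}]
        rows += list(labs)
        return make_bundle(
            patients=[patient("a", birth="1950-06-01", sex="F")],
            labs=rows, codes=codes, prescriptions=prescriptions,
        )

    ENTRY = "2009-06-01"

    def test_two_prescriptions_set_medication_flag(self):
        bundle = self.base_bundle(prescriptions=[
            {"id": "a", "date": "2009-01-05", "drug_class": "nsaid"},
            {"id": "a", "date": "2009-04-01", "drug_class": "nsaid"},
        ])
        assert extract_predictors(bundle, "a", self.ENTRY)["nsaid"] == 1.0

    def test_single_prescription_insufficient(self):
        bundle = self.base_bundle(prescriptions=[
            {"id": "a", "date": "2009-04-01", "drug_class": "nsaid"},
        ])
        assert extract_predictors(bundle, "a", self.ENTRY)["nsaid"] == 0.0

    def test_prescriptions_outside_six_months_ignored(self):
        bundle = self.base_bundle(prescriptions=[
            {"id": "a", "date": "2008-09-01", "drug_class": "nsaid"},
            {"id": "a", "date": "2008-10-01", "drug_class": "nsaid"},
        ])
        assert extract_predictors(bundle, "a", self.ENTRY)["nsaid"] == 0.0

    def test_stale_lab_is_missing(self):
        bundle = self.base_bundle(labs=[
            {"id": "a", "date": "2008-04-01", "analyte": "sbp", "value": 150.0},
        ])
        assert np.isnan(extract_predictors(bundle, "a", self.ENTRY)["sbp"])

    def test_most_recent_lab_wins(self):
        bundle = self.base_bundle(labs=[
            {"id": "a", "date": "2008-12-01", "analyte": "sbp", "value": 150.0},
            {"id": "a", "date": "2009-04-01", "analyte": "sbp", "value": 120.0},
        ])
        assert extract_predictors(bundle, "a", self.ENTRY)["sbp"] == 120.0

    def test_entry_day_lab_excluded_from_lookback(self):
        bundle = self.base_bundle(labs=[
            {"id": "a", "date": "2009-06-01", "analyte": "sbp", "value": 150.0},
        ])
        assert np.isnan(extract_predictors(bundle, "a", self.ENTRY)["sbp"])

    def test_comorbidity_code_before_entry(self):
        bundle = self.base_bundle(codes=[
            {"id": "a", "date": "2001-01-01", "code_class": "hypertension"},
        ])
        assert extract_predictors(bundle, "a", self.ENTRY)["hypertension"] == 1.0

    def test_unspecified_diabetes_typed_by_age_at_first_code(self):
        young = self.base_bundle(codes=[
            {"id": "a", "date": "1980-01-01", "code_class": "diabetes_unspecified"},
        ])
        pred = extract_predictors(young, "a", self.ENTRY)
        assert pred["diabetes_t1"] == 1.0 and pred["diabetes_t2"] == 0.0
        old = self.base_bundle(codes=[
            {"id": "a", "date": "1991-01-01", "code_class": "diabetes_unspecified"},
        ])
        pred = extract_predictors(old, "a", self.ENTRY)
        assert pred["diabetes_t1"] == 0.0 and pred["diabetes_t2"] == 1.0

    def test_conflicting_diabetes_codes_resolved_by_age_rule(self):
        bundle = self.base_bundle(codes=[
            {"id": "a", "date": "1995-01-01", "code_class": "diabetes_t1"},
            {"id": "a", "date": "2000-01-01", "code_class": "diabetes_t2"},
        ])
        pred = extract_predictors(bundle, "a", self.ENTRY)  # first code at age 44
        assert pred["diabetes_t2"] == 1.0 and pred["diabetes_t1"] == 0.0

    def test_anaemia_from_haemoglobin_by_sex(self):
        bundle = self.base_bundle(labs=[
            {"id": "a", "date": "2009-04-01", "analyte": "haemoglobin", "value": 12.5},
        ])
        # female threshold is 12: hb 12.5 is not anaemic
        assert extract_predictors(bundle, "a", self.ENTRY)["anaemia"] == 0.0

    def test_missing_ethnicity_defaults_to_white(self):
        bundle = make_bundle(
            patients=[patient("a", birth="1950-06-01", ethnicity=None)],
            labs=[{"id": "a", "date": "2009-06-01", "analyte": "creatinine", "value": 1.0}],
        )
        pred = extract_predictors(bundle, "a", self.ENTRY)
        assert pred["ethnicity"] == "white" and pred["white"] == 1.0

    def test_unknown_patient_rejected(self):
        with pytest.raises(KeyError):
            extract_predictors(self.base_bundle(), "nobody", self.ENTRY)


class TestNiceRiskGroup:
    def test_hypertension_alone_qualifies(self):
        assert flag_nice_risk_group({"hypertension": 1.0})

    def test_recent_aki_qualifies_but_stale_does_not(self):
        assert flag_nice_risk_group({"aki_2yr": 1.0})
        assert not flag_nice_risk_group({"aki_2yr": 0.0})

    def test_aki_window_enforced_in_extraction(self):
        bundle = make_bundle(
            patients=[patient("a", birth="1950-06-01")],
            labs=[{"id": "a", "date": "2009-06-01", "analyte": "creatinine", "value": 1.0}],
            codes=[{"id": "a", "date": "2006-06-01", "code_class": "aki"}],
        )
        pred = extract_predictors(bundle, "a", "2009-06-01")
        assert pred["aki_2yr"] == 0.0  # three years pre-entry
        assert not flag_nice_risk_group(pred)

    def test_no_factors(self):
        assert not flag_nice_risk_group({"hypertension": 0.0, "nsaid": 0.0})
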