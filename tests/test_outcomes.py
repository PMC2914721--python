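import logging

import numpy as np
import pandas as pd
import pytest

from dfi.cohort import build_cohort
from dfi.outcomes import (
    current_amputation_in,
    detect_current_amputation,
    ltc_transition,
    mortality,
    outcome_table,
    outcomes_frame,
    readmissions,
    readmit_pairs,
    subsequent_amputation,
)

from conftest import make_bundle


def _one_patient_bundle(extra_stays=(), extra_dx=(), extra_procs=(), extra_visits=(),
                        death_date=""):
    """Index ulcer stay 2001-03-01 .. 2001-03-11, plus supplied follow-up."""
    stays = [
        {"stay_id": "S1", "patient_id": "P1", "admit_date": "2001-03-01",
         "discharge_date": "2001-03-11", "care_setting": "ACUTE"},
        *extra_stays,
    ]
    dx = [{"stay_id": "S1", "position": 1, "icd9_code": "70714"}, *extra_dx]
    return make_bundle(
        patients=[{"patient_id": "P1", "sex": "M", "birth_date": "1940-01-01",
                   "race": "WHITE", "death_date": death_date}],
        stays=stays,
        stay_dx=dx,
        stay_proc=list(extra_procs),
        visits=list(extra_visits),
    )


def _cohort(bundle, registry):
    return build_cohort(bundle, registry)


class TestReadmissions:
    def test_interval_is_admit_minus_index_discharge(self, registry):
        bundle = _one_patient_bundle(
            extra_stays=[{"stay_id": "S2", "patient_id": "P1",
                          "admit_date": "2001-04-10", "discharge_date": "2001-04-15",
                          "care_setting": "ACUTE"}],
            extra_dx=[{"stay_id": "S2", "position": 1, "icd9_code": "44024"}],
        )
        cohort = _cohort(bundle, registry)
        out = readmissions(cohort, bundle, registry).iloc[0]
        assert out["readmitted"]
        assert out["days_to_readmit"] == 30
        assert out["readmit_group"] == "GANGRENE"

    def test_admit_to_admit_option(self, registry):
        bundle = _one_patient_bundle(
            extra_stays=[{"stay_id": "S2", "patient_id": "P1",
                          "admit_date": "2001-04-10", "discharge_date": "2001-04-15",
                          "care_setting": "ACUTE"}],
            extra_dx=[{"stay_id": "S2", "position": 1, "icd9_code": "44024"}],
        )
        cohort = _cohort(bundle, registry)
        out = readmissions(cohort, bundle, registry, interval="admit_to_admit").iloc[0]
        assert out["days_to_readmit"] == 40

    def test_no_later_infection_stay(self, registry):
        bundle = _one_patient_bundle()
        out = readmissions(_cohort(bundle, registry), bundle, registry).iloc[0]
        assert not out["readmitted"]
        assert pd.isna(out["days_to_readmit"])

    def test_overlapping_stay_skipped_with_warning(self, registry, caplog):
        bundle = _one_patient_bundle(
            extra_stays=[{"stay_id": "S2", "patient_id": "P1",
                          "admit_date": "2001-03-05", "discharge_date": "2001-03-20",
                          "care_setting": "ACUTE"}],
            extra_dx=[{"stay_id": "S2", "position": 1, "icd9_code": "44024"}],
        )
        cohort = _cohort(bundle, registry)
        with caplog.at_level(logging.WARNING):
            out = readmissions(cohort, bundle, registry).iloc[0]
        assert not out["readmitted"]
        assert any("overlap" in r.message for r in caplog.records)

    def test_pairs_table(self, registry):
        bundle = _one_patient_bundle(
            extra_stays=[{"stay_id": "S2", "patient_id": "P1",
                          "admit_date": "2001-04-10", "discharge_date": "2001-04-15",
                          "care_setting": "ACUTE"}],
            extra_dx=[{"stay_id": "S2", "position": 1, "icd9_code": "44024"}],
        )
        cohort = _cohort(bundle, registry)
        pairs = readmit_pairs(cohort, readmissions(cohort, bundle, registry))
        assert pairs.iloc[0].tolist() == ["ULCER", "GANGRENE", 1, 30.0]


class TestAmputation:
    def test_current_amputation_codes(self, registry):
        assert current_amputation_in({"8413"}, registry)
        assert not current_amputation_in({"8410"}, registry)  # outside 84.11-17
        assert not current_amputation_in(set(), registry)

    def test_detect_on_index_stay(self, registry):
        bundle = _one_patient_bundle(
            extra_procs=[{"stay_id": "S1", "icd9_proc_code": "8413"}]
        )
        cohort = _cohort(bundle, registry)
        assert detect_current_amputation(cohort, bundle, registry).iloc[0]

    @pytest.mark.parametrize(
        "day,expect_90,expect_365",
        [(45, True, True), (200, False, True), (400, False, False)],
    )
    def test_subsequent_windows(self, registry, day, expect_90, expect_365):
        admit = (pd.Timestamp("2001-03-11") + pd.Timedelta(days=day)).date().isoformat()
        disch = (pd.Timestamp(admit) + pd.Timedelta(days=5)).date().isoformat()
        bundle = _one_patient_bundle(
            extra_stays=[{"stay_id": "S2", "patient_id": "P1", "admit_date": admit,
                          "discharge_date": disch, "care_setting": "ACUTE"}],
            extra_dx=[{"stay_id": "S2", "position": 1, "icd9_code": "25000"}],
            extra_procs=[{"stay_id": "S2", "icd9_proc_code": "8411"}],
        )
        cohort = _cohort(bundle, registry)
        out = subsequent_amputation(cohort, bundle, registry).iloc[0]
        assert out["amputation_90d"] == expect_90
        assert out["amputation_365d"] == expect_365
        assert out["amputation_ever"]

    def test_amputation_during_index_stay_not_subsequent(self, registry):
        bundle = _one_patient_bundle(
            extra_procs=[{"stay_id": "S1", "icd9_proc_code": "8411"}]
        )
        cohort = _cohort(bundle, registry)
        out = subsequent_amputation(cohort, bundle, registry).iloc[0]
        assert not out["amputation_ever"]


class TestLtcTransition:
    def _bundle_with_ltc(self, day=30, setting="LTC_INPATIENT", prior=False):
        extra_stays, extra_visits = [], []
        if setting == "LTC_INPATIENT":
            admit = (pd.Timestamp("2001-03-11") + pd.Timedelta(days=day)).date().isoformat()
            extra_stays.append({"stay_id": "S9", "patient_id": "P1", "admit_date": admit,
                                "discharge_date": admit, "care_setting": "LTC_INPATIENT"})
        else:
            vd = (pd.Timestamp("2001-03-11") + pd.Timedelta(days=day)).date().isoformat()
            extra_visits.append({"visit_id": "V9", "patient_id": "P1", "visit_date": vd,
                                 "care_setting": "LTC_OUTPATIENT"})
        if prior:
            extra_stays.append({"stay_id": "S8", "patient_id": "P1",
                                "admit_date": "1999-06-01", "discharge_date": "1999-08-01",
                                "care_setting": "LTC_INPATIENT"})
        return _one_patient_bundle(extra_stays=extra_stays, extra_visits=extra_visits)

    def test_inpatient_ltc_within_90_days(self, registry):
        bundle = self._bundle_with_ltc(day=30)
        cohort = _cohort(bundle, registry)
        out = ltc_transition(cohort, bundle).iloc[0]
        assert out["ltc_90d"] and out["ltc_365d"]

    def test_prior_ltc_patients_undefined(self, registry):
        bundle = self._bundle_with_ltc(day=30, prior=True)
        cohort = _cohort(bundle, registry)
        assert cohort.iloc[0]["prior_ltc"]
        out = ltc_transition(cohort, bundle).iloc[0]
        assert pd.isna(out["ltc_90d"]) and pd.isna(out["ltc_365d"])

    def test_outpatient_only_invisible_to_inpatient_variant(self, registry):
        bundle = self._bundle_with_ltc(day=30, setting="LTC_OUTPATIENT")
        cohort = _cohort(bundle, registry)
        any_ltc = ltc_transition(cohort, bundle).iloc[0]
        inpatient = ltc_transition(cohort, bundle, inpatient_only=True).iloc[0]
        assert any_ltc["ltc_90d"]
        assert not inpatient["ltc_inpatient_90d"]


class TestMortality:
    def test_death_within_90_days(self, registry):
        bundle = _one_patient_bundle(death_date="2001-05-30")  # 80 days post
        out = mortality(_cohort(bundle, registry), bundle).iloc[0]
        assert out["death_90d"] and out["death_365d"] and out["death_ever"]
        assert not out["in_hospital_death"]

    def test_no_death_date(self, registry):
        bundle = _one_patient_bundle()
        out = mortality(_cohort(bundle, registry), bundle).iloc[0]
        assert not out[["death_90d", "death_365d", "death_ever"]].any()

    def test_death_on_discharge_day_is_in_hospital(self, registry):
        bundle = _one_patient_bundle(death_date="2001-03-11")
        out = mortality(_cohort(bundle, registry), bundle).iloc[0]
        assert out["in_hospital_death"]
        assert not out["death_90d"] and not out["death_ever"]


class TestOutcomeAssembly:
    def test_monotone_windows_on_simulated_cohort(self, registry, sim_small):
        bundle, _ = sim_small
        cohort = build_cohort(bundle, registry)
        out = outcomes_frame(cohort, bundle, registry)
        assert (~out["amputation_90d"] | out["amputation_365d"]).all()
        assert (~out["amputation_365d"] | out["amputation_ever"]).all()
        assert (~out["death_90d"] | out["death_365d"]).all()
        defined = out["ltc_90d"].notna()
        assert (
            ~out.loc[defined, "ltc_90d"].astype(bool)
            | out.loc[defined, "ltc_365d"].astype(bool)
        ).all()

    def test_no_outcome_precedes_discharge(self, registry, sim_small):
        bundle, _ = sim_small
        cohort = build_cohort(bundle, registry)
        out = outcomes_frame(cohort, bundle, registry)
        merged = out.merge(
            cohort[["patient_id", "index_discharge_date"]], on="patient_id"
        )
        has = merged["first_amputation_date"].notna()
        assert (
            merged.loc[has, "first_amputation_date"]
            > merged.loc[has, "index_discharge_date"]
        ).all()
        re = merged["readmitted"]
        assert (merged.loc[re, "days_to_readmit"] >= 0).all()

    def test_outcome_table_degenerate_groups(self, registry):
        bundle = _one_patient_bundle()
        cohort = _cohort(bundle, registry)
        out = outcomes_frame(cohort, bundle, registry)
        tab = outcome_table(cohort, out)
        assert tab.loc["ULCER", "amputation"] in (0.0, 1.0)
        assert tab.loc["ULCER", "death"] == 0.0
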