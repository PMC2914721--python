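import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfi.classify import (
    build_flow,
    classify_codes,
    classify_patient,
    classify_stays_frame,
    coinfection_matrix,
)
from dfi.codes import RANKED_CATEGORIES, SEVERITY_RANK, InfectionCategory, Specificity
from dfi.cohort import InpatientStay

C = InfectionCategory

# one unconditional specific code per category
REP = {
    C.GANGRENE: "44024",
    C.OSTEOMYELITIS: "73007",
    C.ULCER: "70714",
    C.FOOT_CELLULITIS_ABSCESS: "6827",
    C.TOE_CELLULITIS_ABSCESS: "68110",
    C.PARONYCHIA: "68111",
}
# moderate-tier codes and the category they suggest
MODERATE = {
    C.OSTEOMYELITIS: "73026",
    C.ULCER: "70710",
    C.FOOT_CELLULITIS_ABSCESS: "6826",
}


class TestClassifyCodes:
    def test_most_severe_wins_ulcer_over_cellulitis(self, registry):
        got = classify_codes({"70714", "6827"}, registry)
        assert got.category is C.ULCER
        assert got.coexisting == {C.FOOT_CELLULITIS_ABSCESS}
        assert not got.excluded_by_moderate

    def test_gangrene_with_companion_over_osteomyelitis(self, registry):
        got = classify_codes({"7854", "2507", "73007"}, registry)
        assert got.category is C.GANGRENE
        assert got.coexisting == {C.OSTEOMYELITIS}

    def test_no_codes_is_none(self, registry):
        assert classify_codes(set(), registry).category is C.NONE

    def test_moderate_only_is_other(self, registry):
        got = classify_codes({"6826"}, registry)
        assert got.category is C.OTHER
        assert got.final_group is C.OTHER

    def test_moderate_code_for_more_severe_type_excludes(self, registry):
        got = classify_codes({"6827", "73026"}, registry)
        assert got.category is C.FOOT_CELLULITIS_ABSCESS
        assert got.excluded_by_moderate
        assert got.final_group is C.OTHER

    @pytest.mark.parametrize("spec_cat", sorted(REP, key=SEVERITY_RANK.get))
    @pytest.mark.parametrize("mod_cat", sorted(MODERATE, key=SEVERITY_RANK.get))
    def test_exclusion_rule_over_all_category_pairs(self, registry, spec_cat, mod_cat):
        got = classify_codes({REP[spec_cat], MODERATE[mod_cat]}, registry)
        should_exclude = SEVERITY_RANK[mod_cat] > SEVERITY_RANK[spec_cat]
        assert got.excluded_by_moderate == should_exclude
        assert got.final_group is (C.OTHER if should_exclude else spec_cat)

    def test_agrees_with_max_rank_oracle_on_all_64_subsets(self, registry):
        cats = list(REP)
        for k in range(len(cats) + 1):
            for subset in itertools.combinations(cats, k):
                codes = {REP[c] for c in subset}
                got = classify_codes(codes, registry)
                if not subset:
                    assert got.category is C.NONE
                    continue
                oracle = max(subset, key=lambda c: SEVERITY_RANK[c])
                assert got.category is oracle
                assert got.coexisting == set(subset) - {oracle}

    @given(
        subset=st.sets(st.sampled_from(sorted(REP, key=str)), min_size=1),
        dup=st.integers(1, 3),
        seed=st.integers(0, 10_000),
    )
    @settings(derandomize=True, max_examples=60)
    def test_invariant_to_order_and_duplication(self, registry, subset, dup, seed):
        codes = [REP[c] for c in subset] * dup
        rng = np.random.default_rng(seed)
        rng.shuffle(codes)
        got = classify_codes(codes, registry)
        ref = classify_codes({REP[c] for c in subset}, registry)
        assert got.category is ref.category and got.coexisting == ref.coexisting

    def test_hierarchy_exclusivity(self, registry):
        got = classify_codes(set(REP.values()), registry)
        assert got.category not in got.coexisting
        assert all(
            SEVERITY_RANK[c] < SEVERITY_RANK[got.category] for c in got.coexisting
        )


class TestClassifyPatient:
    def _stay(self, sid, day, codes):
        import datetime as dt

        d = dt.date(2001, 1, 1) + dt.timedelta(days=day)
        return InpatientStay(
            stay_id=sid,
            patient_id="P1",
            admit_date=d,
            discharge_date=d + dt.timedelta(days=3),
            diagnoses=tuple((i + 1, c) for i, c in enumerate(codes)),
        )

    def test_index_stay_mode_uses_first_qualifying_stay(self, registry):
        stays = [self._stay("S1", 0, ["68110"]), self._stay("S2", 30, ["70715"])]
        got = classify_patient(stays, registry, mode="index_stay")
        assert got.category is C.TOE_CELLULITIS_ABSCESS
        assert got.stay_id == "S1"

    def test_pooled_mode_unions_all_codes(self, registry):
        stays = [self._stay("S1", 0, ["68110"]), self._stay("S2", 30, ["70715"])]
        assert classify_patient(stays, registry, mode="pooled").category is C.ULCER

    def test_gas_gangrene_is_gangrene(self, registry):
        assert (
            classify_patient([self._stay("S1", 0, ["0400"])], registry).category
            is C.GANGRENE
        )

    def test_non_qualifying_stays_skipped(self, registry):
        stays = [self._stay("S1", 0, ["25000"]), self._stay("S2", 30, ["6827"])]
        got = classify_patient(stays, registry)
        assert got.stay_id == "S2"

    def test_error_when_no_infection_code(self, registry):
        with pytest.raises(ValueError):
            classify_patient([self._stay("S1", 0, ["25000"])], registry)


class TestVectorizedAgreement:
    def test_frame_path_matches_per_set_path(self, registry, sim_small):
        bundle, _ = sim_small
        frame = classify_stays_frame(bundle.stay_dx, registry).set_index("stay_id")
        by_stay = bundle.stay_dx.groupby("stay_id")["icd9_code"].apply(set)
        checked = 0
        for stay_id, codes in by_stay.items():
            ref = classify_codes(codes, registry)
            if ref.category is C.NONE:
                assert stay_id not in frame.index
                continue
            row = frame.loc[stay_id]
            assert row["category"] == ref.category.value
            assert row["final_group"] == ref.final_group.value
            assert row["excluded_by_moderate"] == ref.excluded_by_moderate
            got_coex = set(row["coexisting"].split(";")) - {""}
            assert got_coex == {c.value for c in ref.coexisting}
            checked += 1
        assert checked > 500


class TestCoinfectionMatrix:
    def _cls(self, cat, coexisting=()):
        from dfi.classify import StayClassification

        return StayClassification(
            stay_id=None, category=cat, coexisting=frozenset(coexisting)
        )

    def test_hand_count(self, registry):
        cls = [self._cls(C.GANGRENE, [C.ULCER])] + [self._cls(C.GANGRENE)] * 3
        m = coinfection_matrix(cls)
        assert m.loc["ULCER", "GANGRENE"] == pytest.approx(0.25)

    def test_all_single_infection_gives_zeros(self):
        m = coinfection_matrix([self._cls(C.GANGRENE)] * 5 + [self._cls(C.ULCER)] * 5)
        assert (m.fillna(0).to_numpy() == 0).all()

    def test_cells_at_or_above_diagonal_absent(self):
        m = coinfection_matrix([self._cls(c) for c in REP])
        for r in RANKED_CATEGORIES:
            for g in RANKED_CATEGORIES:
                if SEVERITY_RANK[r] >= SEVERITY_RANK[g]:
                    assert pd.isna(m.loc[r.value, g.value])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            coinfection_matrix([])

    def test_other_category_rejected(self):
        with pytest.raises(ValueError):
            coinfection_matrix([self._cls(C.OTHER)])


class TestBuildFlow:
    def _cls(self, cat, **kw):
        from dfi.classify import StayClassification

        return StayClassification(stay_id=None, category=cat, **kw)

    def test_counts(self):
        cls = [self._cls(C.ULCER)] * 3 + [self._cls(C.OTHER)] * 2
        flow = build_flow(cls)
        assert flow.n_total == 5
        assert flow.n_per_category[C.ULCER] == 3
        assert flow.n_other == 2

    def test_empty(self):
        flow = build_flow([])
        assert flow.n_total == 0 and flow.n_other == 0

    def test_excluded_counts_into_other(self):
        cls = [
            self._cls(C.ULCER, excluded_by_moderate=True),
            self._cls(C.ULCER),
        ]
        flow = build_flow(cls)
        assert flow.n_other == 1
        assert flow.n_per_category[C.ULCER] == 1
        assert flow.n_excluded_by_moderate[C.ULCER] == 1

    def test_partition_on_simulated_cohort(self, registry, sim_small):
        bundle, truth = sim_small
        frame = classify_stays_frame(bundle.stay_dx, registry)
        # every simulated patient with an infection code lands in exactly
        # one of the six groups or OTHER
        finals = frame["final_group"].unique()
        assert set(finals) <= {c.value for c in RANKED_CATEGORIES} | {"OTHER"}
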