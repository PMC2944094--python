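"""Standardization: expected counts, SIR CIs, direct rates, Carstairs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rifkit.health import CountTable, PopulationTable
from rifkit.standardize import (
    ReferenceRates,
    byar_ci,
    carstairs_index,
    direct_rate,
    exact_poisson_ci,
    expected_count,
    indirect_ratio,
)

BANDS = ("0-4", "5-9")


def _pop(rows):
    return PopulationTable(pd.DataFrame(rows), band_list=BANDS)


def _counts(rows):
    return CountTable(pd.DataFrame(rows), band_list=BANDS)


def _ref(rates):
    return ReferenceRates(pd.DataFrame(rates), strata=("sex", "age_band"))


class TestExpectedCount:
    def test_single_stratum_product(self):
        pop = _pop([{"area_id": "A", "sex": "male", "age_band": "0-4",
                     "year": 2001, "person_years": 1000.0}])
        ref = _ref([{"sex": "male", "age_band": "0-4", "rate": 0.005}])
        assert expected_count(pop, ref) == pytest.approx(5.0)

    def test_two_strata_hand_sum(self):
        pop = _pop([
            {"area_id": "A", "sex": "male", "age_band": "0-4", "year": 2001,
             "person_years": 100.0},
            {"area_id": "A", "sex": "male", "age_band": "5-9", "year": 2001,
             "person_years": 200.0},
        ])
        ref = _ref([{"sex": "male", "age_band": "0-4", "rate": 0.01},
                    {"sex": "male", "age_band": "5-9", "rate": 0.02}])
        assert expected_count(pop, ref) == pytest.approx(5.0)  # 1 + 4

    def test_study_equals_reference_gives_reference_total(self):
        # When the study population IS the reference population, E equals
        # the reference observed total.
        pop = _pop([
            {"area_id": "A", "sex": s, "age_band": b, "year": 2001,
             "person_years": py}
            for s, b, py in [("male", "0-4", 500.0), ("male", "5-9", 1500.0),
                             ("female", "0-4", 800.0)]
        ])
        counts = _counts([
            {"area_id": "A", "sex": s, "age_band": b, "year": 2001, "events": o}
            for s, b, o in [("male", "0-4", 5), ("male", "5-9", 30),
                            ("female", "0-4", 4)]
        ])
        ref = ReferenceRates.from_tables(counts, pop)
        assert expected_count(pop, ref) == pytest.approx(39.0)

    def test_missing_stratum_named(self):
        pop = _pop([{"area_id": "A", "sex": "female", "age_band": "5-9",
                     "year": 2001, "person_years": 10.0}])
        ref = _ref([{"sex": "male", "age_band": "0-4", "rate": 0.01}])
        with pytest.raises(ValueError, match="female.*5-9"):
            expected_count(pop, ref)

    def test_additive_over_area_sets(self, small_study):
        e = expected_count(small_study.population, small_study.reference,
                           by_area=True)
        total = expected_count(small_study.population, small_study.reference)
        assert e.sum() == pytest.approx(total)
        half = list(e.index)[:18]
        assert e.loc[half].sum() + e.drop(half).sum() == pytest.approx(total)

    def test_constant_covariate_is_adjustment_noop(self, small_study):
        # A covariate quintile constant across all areas adds nothing beyond
        # age-sex adjustment.
        pop_q = small_study.population.data.copy()
        pop_q["quintile"] = 3
        ref_q = small_study.reference.data.copy()
        ref_q["quintile"] = 3
        e_base = expected_count(small_study.population, small_study.reference,
                                by_area=True)
        e_q = expected_count(
            PopulationTable(pop_q, band_list=small_study.population.band_list),
            ReferenceRates(ref_q, strata=("sex", "age_band", "quintile")),
            by_area=True,
        )
        assert np.allclose(e_base.sort_index(), e_q.sort_index())


class TestIndirectRatio:
    def test_ratio_is_o_over_e(self):
        r = indirect_ratio(103, 101.88)
        assert r.ratio == pytest.approx(103 / 101.88)

    def test_zero_count_convention(self):
        r = indirect_ratio(0, 3.0)
        assert r.ratio == 0.0
        assert r.ci[0] == 0.0
        assert r.ci[1] == pytest.approx(byar_ci(0, 3.0)[1])
        assert r.ci[1] > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            indirect_ratio(5, 0.0)
        with pytest.raises(ValueError):
            indirect_ratio(-1, 3.0)
        with pytest.raises(ValueError):
            indirect_ratio(5, 3.0, method="wald")

    def test_exact_counts_give_ratio_one(self, small_study):
        # O generated as exactly n_s * r_s sums to E: ratio 1 exactly.
        e = expected_count(small_study.population, small_study.reference)
        r = indirect_ratio(int(round(e)), e)
        assert r.ratio == pytest.approx(round(e) / e)

    @pytest.mark.parametrize("o", range(20, 2001, 90))
    def test_byar_close_to_exact_poisson(self, o):
        e = o / 1.2
        b = byar_ci(o, e)
        x = exact_poisson_ci(o, e)
        assert b[0] == pytest.approx(x[0], abs=0.01)
        assert b[1] == pytest.approx(x[1], abs=0.01)

    def test_ci_width_decreasing_in_o_at_fixed_ratio(self):
        widths = []
        for o in [10, 30, 100, 300, 1000, 3000]:
            ci = byar_ci(o, o / 1.3)
            widths.append(ci[1] - ci[0])
        assert all(b < a for a, b in zip(widths, widths[1:]))

    @given(st.integers(1, 5000), st.floats(0.2, 5.0))
    def test_ci_brackets_ratio(self, o, ratio):
        e = o / ratio
        r = indirect_ratio(o, e)
        assert r.ci[0] <= r.ratio <= r.ci[1]


class TestDirectRate:
    def test_constant_rate_identity(self):
        # If every stratum rate is r, any weights give per * r.
        pop = _pop([
            {"area_id": "A", "sex": "male", "age_band": "0-4", "year": 2001,
             "person_years": 1000.0},
            {"area_id": "A", "sex": "male", "age_band": "5-9", "year": 2001,
             "person_years": 4000.0},
        ])
        counts = _counts([
            {"area_id": "A", "sex": "male", "age_band": "0-4", "year": 2001,
             "events": 10},
            {"area_id": "A", "sex": "male", "age_band": "5-9", "year": 2001,
             "events": 40},
        ])
        w = {("male", "0-4"): 0.9, ("male", "5-9"): 0.1}
        res = direct_rate(counts, pop, w, strata=("sex", "age_band"))
        assert res.rate == pytest.approx(1e5 * 0.01)

    def test_standard_equals_study_gives_crude_rate(self):
        pop = _pop([
            {"area_id": "A", "sex": "male", "age_band": "0-4", "year": 2001,
             "person_years": 1000.0},
            {"area_id": "A", "sex": "male", "age_band": "5-9", "year": 2001,
             "person_years": 3000.0},
        ])
        counts = _counts([
            {"area_id": "A", "sex": "male", "age_band": "0-4", "year": 2001,
             "events": 5},
            {"area_id": "A", "sex": "male", "age_band": "5-9", "year": 2001,
             "events": 60},
        ])
        w = {("male", "0-4"): 1000.0, ("male", "5-9"): 3000.0}
        res = direct_rate(counts, pop, w, strata=("sex", "age_band"))
        assert res.rate == pytest.approx(1e5 * 65 / 4000)

    def test_two_strata_hand_value(self):
        pop = _pop([
            {"area_id": "A", "sex": "male", "age_band": "0-4", "year": 2001,
             "person_years": 1000.0},
            {"area_id": "A", "sex": "male", "age_band": "5-9", "year": 2001,
             "person_years": 1000.0},
        ])
        counts = _counts([
            {"area_id": "A", "sex": "male", "age_band": "0-4", "year": 2001,
             "events": 10},
            {"area_id": "A", "sex": "male", "age_band": "5-9", "year": 2001,
             "events": 20},
        ])
        w = {("male", "0-4"): 0.5, ("male", "5-9"): 0.5}
        res = direct_rate(counts, pop, w, strata=("sex", "age_band"))
        assert res.rate == pytest.approx(1500.0)
        assert res.ci[0] <= res.rate <= res.ci[1]

    def test_events_with_zero_person_years(self):
        pop = _pop([{"area_id": "A", "sex": "male", "age_band": "0-4",
                     "year": 2001, "person_years": 0.0}])
        counts = _counts([{"area_id": "A", "sex": "male", "age_band": "0-4",
                           "year": 2001, "events": 3}])
        with pytest.raises(ValueError, match="zero person-years"):
            direct_rate(counts, pop, {("male", "0-4"): 1.0},
                        strata=("sex", "age_band"))


class TestCarstairs:
    COLS = ["male_unemployment", "no_car_access", "low_social_class", "overcrowding"]

    def test_area_at_mean_scores_zero(self):
        df = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.1], [0.3, 0.4, 0.5, 0.3], [0.2, 0.3, 0.4, 0.2]],
            columns=self.COLS, index=["a", "b", "m"],
        )
        idx = carstairs_index(df)
        assert idx["m"] == pytest.approx(0.0)

    def test_mirrored_areas_sum_to_zero(self):
        df = pd.DataFrame([[0.1, 0.2, 0.3, 0.15], [0.5, 0.4, 0.5, 0.25]],
                          columns=self.COLS, index=["a", "b"])
        idx = carstairs_index(df)
        assert idx.sum() == pytest.approx(0.0)

    def test_matches_brute_force_zsum(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.uniform(0, 0.6, size=(5, 4)), columns=self.COLS,
                          index=list("abcde"))
        idx = carstairs_index(df)
        expect = sum(
            (df[c] - df[c].mean()) / df[c].std(ddof=1) for c in self.COLS
        )
        assert np.allclose(idx, expect)

    def test_zero_variance_component_dropped(self):
        df = pd.DataFrame([[0.1, 0.2, 0.3, 0.5], [0.3, 0.4, 0.5, 0.5]],
                          columns=self.COLS, index=["a", "b"])
        with pytest.warns(UserWarning, match="overcrowding"):
            idx = carstairs_index(df)
        expect = sum((df[c] - df[c].mean()) / df[c].std(ddof=1)
                     for c in self.COLS[:3])
        assert np.allclose(idx, expect)

    def test_proportions_enforced(self):
        df = pd.DataFrame([[0.1, 1.2, 0.3, 0.5], [0.3, 0.4, 0.5, 0.1]],
                          columns=self.COLS)
        with pytest.raises(ValueError, match="proportions"):
            carstairs_index(df)
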