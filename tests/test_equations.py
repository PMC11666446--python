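"""Closed-form equation values, invariants and unit conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ebmscale as eb
from ebmscale.records import DomainWarning

REF = eb.Subject(mass=76.6, height=1.75, sex="male", age=20)

anthro = st.tuples(
    st.floats(40, 150),  # mass kg
    st.floats(1.4, 2.1),  # height m
    st.booleans(),  # male
    st.floats(0, 90),  # age years
)


class TestEbmAllometric:
    def test_unit_subject_collapses_to_one(self):
        assert eb.compute_ebm_allometric(eb.Subject(1, 1, "female", 0)) == pytest.approx(1.0)

    def test_reference_subject_value(self):
        # independent log-space hand evaluation:
        # exp(0.63·ln 76.6 + 0.53·ln 1.75 + ln 1.16 − 0.39·0.04)
        assert eb.compute_ebm_allometric(REF) == pytest.approx(23.635, abs=0.05)

    def test_reference_subject_yields_met_constant_11(self):
        ebm = eb.compute_ebm_allometric(REF)
        assert round(3.5 * 76.6 / ebm) == 11

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(anthro)
    def test_log_space_matches_direct_powers(self, a):
        mass, height, male, age = a
        ebm = eb.ebm_allometric(mass, height, male, age)
        direct = (
            mass**0.63 * height**0.53 * (1.16 if male else 1.0)
            * np.exp(-0.39 * (age / 100) ** 2)
        )
        assert ebm == pytest.approx(direct, rel=1e-12)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(anthro, st.floats(1.01, 1.5))
    def test_strictly_monotone_in_mass_and_height(self, a, factor):
        mass, height, male, age = a
        base = eb.ebm_allometric(mass, height, male, age)
        assert eb.ebm_allometric(mass * factor, height, male, age) > base
        assert eb.ebm_allometric(mass, height * factor, male, age) > base
        assert base > 0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(40, 150), st.floats(1.4, 2.1), st.booleans(), st.floats(1, 80))
    def test_strictly_decreasing_in_age(self, mass, height, male, age):
        assert eb.ebm_allometric(mass, height, male, age + 5) < eb.ebm_allometric(
            mass, height, male, age
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(40, 150), st.floats(1.4, 2.1), st.floats(0, 90))
    def test_male_female_ratio_is_exactly_the_sex_factor(self, mass, height, age):
        ratio = eb.ebm_allometric(mass, height, True, age) / eb.ebm_allometric(
            mass, height, False, age
        )
        assert ratio == pytest.approx(1.16, rel=1e-12)

    @pytest.mark.parametrize("mass,height", [(-1, 1.7), (0, 1.7), (70, 0), (70, -2)])
    def test_nonpositive_inputs_rejected(self, mass, height):
        with pytest.raises(ValueError):
            eb.ebm_allometric(mass, height, True, 30)


class TestEbmAdditive:
    def test_printed_male_coefficients(self):
        # −0.58 + 0.18·76.6 + 7.20·1.75 − 0.08·20
        assert eb.compute_ebm_additive(REF) == pytest.approx(24.208, abs=1e-9)

    def test_printed_female_coefficients(self):
        # −0.26 + 0.16·70 + 5.63·1.65 − 0.06·44
        subj = eb.Subject(mass=70, height=1.65, sex="female", age=44)
        assert eb.compute_ebm_additive(subj) == pytest.approx(17.5895, abs=1e-9)

    def test_correlation_with_allometric_over_anthropometric_grid(self):
        # dense grid over mass 50-110 kg, height 1.5-1.95 m, age 18-79,
        # restricted to the plausible BMI window 18.5-40
        mass, height, age = np.meshgrid(
            np.linspace(50, 110, 13), np.linspace(1.5, 1.95, 10), np.linspace(18, 79, 12)
        )
        bulk = (mass / height**2 >= 18.5) & (mass / height**2 <= 40)
        for male in (True, False):
            allo = eb.ebm_allometric(mass, height, male, age)
            add = eb.ebm_additive(mass, height, male, age)
            r = np.corrcoef(allo[bulk].ravel(), add[bulk].ravel())[0, 1]
            assert r > 0.99

    def test_agreement_with_allometric_over_cohort_bulk(self):
        # over a realistic joint anthropometric distribution the additive
        # approximation stays within 10% of the allometric form everywhere
        from ebmscale import CohortSpec, generate_cohort

        df = generate_cohort(CohortSpec.healthy(n=5618), seed=0).df
        add = eb.ebm_additive(
            df["mass_kg"].to_numpy(), df["height_m"].to_numpy(),
            df["sex"].to_numpy(), df["age"].to_numpy(),
        )
        rel = np.abs(add - df["ebm"]) / df["ebm"]
        assert rel.max() < 0.10
        assert np.corrcoef(df["ebm"], add)[0, 1] > 0.99

    def test_extreme_inputs_warn_but_return(self):
        with pytest.warns(DomainWarning):
            val = eb.ebm_additive(0.5, 0.1, False, 90)
        assert val < 0


class TestWorkload:
    def test_rest_is_two_mets(self):
        assert eb.workload_ebm(0, 0, 0) == pytest.approx(2.0)

    def test_hand_arithmetic_at_healthy_means(self):
        # 2 + 5·(1.06 + 0.522) + 0.019·108
        assert eb.workload_ebm(5.0, 0.10, 108) == pytest.approx(11.962, abs=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0.1, 12), st.floats(0, 0.5), st.floats(0, 180))
    def test_strictly_increasing_in_each_input(self, sp, gr, hrr):
        # grade acts through the vertical component Sp·fGr, so speed > 0
        base = eb.workload_ebm(sp, gr, hrr)
        assert eb.workload_ebm(sp + 0.1, gr, hrr) > base
        assert eb.workload_ebm(sp, gr + 0.01, hrr) > base
        assert eb.workload_ebm(sp, gr, hrr + 1) > base

    def test_grade_must_be_fractional(self):
        with pytest.raises(ValueError):
            eb.workload_ebm(5, 11, 100)  # percent passed where fraction expected

    def test_kokkinos_rest_is_one_met(self):
        assert eb.workload_kokkinos(0, 0.2) == pytest.approx(1.0)

    def test_kokkinos_at_healthy_means(self):
        # (129·(0.17 + 0.79·0.11) + 3.5)/3.5
        assert eb.workload_kokkinos(129, 0.11) == pytest.approx(10.4686, abs=1e-3)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            eb.workload_ebm(-1, 0, 0)
        with pytest.raises(ValueError):
            eb.workload_kokkinos(-1, 0)


class TestPredictAndIndex:
    def test_reference_subject_constant_consistency(self):
        # 11·EBM at WL=1 vs 3.5·76.6: agree within rounding of the constant
        ebm = eb.compute_ebm_allometric(REF)
        ratio = (11 * ebm) / (3.5 * 76.6)
        assert 11 / 11.5 < ratio < 11 / 10.5

    def test_total_mass_standard_arithmetic(self):
        subj = eb.Subject(mass=70, height=1.7, sex="female", age=30)
        # WL=10 via explicit comparator speed: 10 METs needs Sp·0.17·m/min... use
        # the ebm workload instead by mixing standards explicitly.
        test = eb.ExerciseTest(speed=0, fractional_grade=0, hrr=0)
        vo2 = eb.predict_vo2peak(subj, test, standard="total_mass")
        assert vo2 == pytest.approx(3.5 * 70 * 1.0)  # comparator WL at rest is 1 MET

    def test_composed_prediction_frozen_regression_value(self):
        # table-mean male through both audited operations, frozen once
        subj = eb.Subject(mass=84, height=1.78, sex="male", age=44)
        test = eb.ExerciseTest(speed=5.4, fractional_grade=0.11, hrr=112)
        wl = 2 + 5.4 * (1.06 + 5.22 * 0.11) + 0.019 * 112
        expected = 11 * eb.compute_ebm_allometric(subj) * wl
        assert eb.predict_vo2peak(subj, test, standard="ebm") == pytest.approx(expected)
        assert eb.predict_vo2peak(subj, test, standard="ebm") == pytest.approx(3391.9, abs=1.0)

    def test_unknown_standard_rejected(self):
        with pytest.raises(ValueError):
            eb.predict_vo2peak(REF, eb.ExerciseTest(0, 0, 0), standard="lbm")

    def test_index_by_mass_matches_table_division(self):
        subj = eb.Subject(mass=78, height=1.73, sex="male", age=44)
        assert eb.index_vo2peak(2747, subj, scaler="mass") == pytest.approx(35.2, abs=0.05)

    def test_met_display_is_definitional(self):
        subj = eb.Subject(mass=80, height=1.8, sex="male", age=30)
        assert eb.index_vo2peak(3.5 * 80, subj, "mass", met_display=True) == pytest.approx(1.0)
        ebm = eb.compute_ebm_allometric(subj)
        assert eb.index_vo2peak(11 * ebm, subj, "ebm") == pytest.approx(11.0)
        assert eb.index_vo2peak(11 * ebm, subj, "ebm", met_display=True) == pytest.approx(1.0)


class TestCompartmentsAndConversions:
    def test_unit_ebm(self):
        assert eb.lbm_equivalent(1.0) == pytest.approx(1.61)
        assert eb.bcm_scale(1.0) == pytest.approx(1.0)

    def test_bcm_scale_hand_value(self):
        assert eb.bcm_scale(23.6) == pytest.approx(23.6**1.11, rel=1e-12)
        assert eb.bcm_scale(23.6) == pytest.approx(33.4, abs=0.1)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(1, 60))
    def test_lbm_equivalent_is_linear(self, x):
        assert eb.lbm_equivalent(2 * x) == pytest.approx(2 * eb.lbm_equivalent(x), rel=1e-12)

    def test_nonpositive_ebm_rejected(self):
        for fn in (eb.lbm_equivalent, eb.bcm_scale):
            with pytest.raises(ValueError):
                fn(0)

    def test_speed_conversion_round_trip(self):
        assert eb.mph_to_m_per_min(1.0) == pytest.approx(26.8224)
        assert eb.m_per_min_to_mph(eb.mph_to_m_per_min(5.4)) == pytest.approx(5.4, rel=1e-12)

    @pytest.mark.parametrize(
        "per_kg,mets", [(35.6, 10.2), (40.0, 11.4), (29.9, 8.5), (25.9, 7.4)]
    )
    def test_relative_vo2_to_mets_matches_printed_rows(self, per_kg, mets):
        assert round(eb.vo2_to_mets(per_kg), 1) == mets


def test_subject_rejects_centimetre_heights():
    with pytest.raises(ValueError, match="centimetres"):
        eb.Subject(mass=70, height=175, sex="female", age=30)


def test_constants_override_and_unknown_key():
    c = eb.ScalingConstants().replace(mass_exp=0.7)
    assert c.mass_exp == 0.7
    with pytest.raises(ValueError, match="unknown"):
        eb.ScalingConstants().replace(massexp=0.7)
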