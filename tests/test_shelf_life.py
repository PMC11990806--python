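"""Van't Hoff prediction/refinement and the Arrhenius validity check."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoshelf.data_model_io import MINUTES_PER_DAY
from nanoshelf.shelf_life import (
    R_GAS,
    ArrheniusPoint,
    BracketingError,
    VantHoffModel,
    activation_energy,
    closed_form_coefficient,
    predict_time,
    predict_time_days,
    q10_equivalent,
    rate_constant_from_stage,
    refine_coefficient,
    shelf_life_table,
    vant_hoff_validity,
)
from nanoshelf.staging import LinearFit


class TestPredict:
    @pytest.mark.parametrize(
        "A,t_ref,T_target,expected_days",
        [
            (2.5, 38.9, 8, 7.9),     # initial guess on the iron criterion
            (3.0, 38.9, 8, 24.5),    # selection-grid row
            (3.15, 120.0, 8, 102.4),  # full 2 h aging window
            (3.15, 37.0, 8, 31.6),   # size criterion, initial coefficient
            (3.91, 37.0, 8, 120.6),  # size criterion, refined
            (3.91, 37.0, 25, 11.9),
            (3.91, 37.0, 37, 2.3),
        ],
    )
    def test_stress_to_storage_worked_examples(self, A, t_ref, T_target, expected_days):
        model = VantHoffModel(A=A, T_ref_C=70, t_ref_min=t_ref)
        assert round(predict_time_days(model, T_target), 1) == expected_days

    def test_downward_extrapolation_from_cold_anchor(self):
        # albumin-free suspension: 80 days at 8 C shrinks to 2.5 days at 37 C
        model = VantHoffModel(A=3.32, T_ref_C=8, t_ref_min=80 * MINUTES_PER_DAY)
        assert round(predict_time_days(model, 37), 1) == 2.5
        assert predict_time_days(model, 25) == pytest.approx(10.3, abs=0.15)

    def test_reference_temperature_is_identity(self):
        model = VantHoffModel(A=3.15, T_ref_C=70, t_ref_min=38.9)
        assert predict_time(model, 70) == 38.9

    @settings(derandomize=True, max_examples=50)
    @given(
        A=st.floats(1.1, 5.0),
        a=st.floats(-40.0, 40.0),
        b=st.floats(-40.0, 40.0),
    )
    def test_composition_through_intermediate_temperature(self, A, a, b):
        """Extrapolating 70 -> 70-a -> 70-a-b equals direct 70 -> 70-a-b."""
        m = VantHoffModel(A=A, T_ref_C=70, t_ref_min=38.9)
        via = predict_time(m, 70 - a)
        m2 = VantHoffModel(A=A, T_ref_C=70 - a, t_ref_min=via)
        direct = predict_time(m, 70 - a - b)
        assert predict_time(m2, 70 - a - b) == pytest.approx(direct, rel=1e-12)


class TestRefine:
    def test_iron_criterion_refines_to_paper_coefficient(self):
        a = refine_coefficient(38.9, 70, 32.9 * MINUTES_PER_DAY, 8)
        assert round(a, 2) == 3.15

    def test_size_criterion_refines_to_paper_coefficient(self):
        a = refine_coefficient(37.0, 70, 120.5 * MINUTES_PER_DAY, 8)
        assert round(a, 2) == 3.91

    @pytest.mark.parametrize("a0", [1.5, 2.5, 3.15, 3.91, 5.0])
    def test_refine_inverts_predict(self, a0):
        model = VantHoffModel(A=a0, T_ref_C=70, t_ref_min=38.9)
        observed = predict_time(model, 8)
        a = refine_coefficient(38.9, 70, observed, 8, bounds=(1.2, 6.0))
        assert a == pytest.approx(a0, rel=1e-6)

    def test_bisection_matches_closed_form_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a0 = rng.uniform(1.6, 5.5)
            t_ref = rng.uniform(10, 200)
            dT = rng.uniform(20, 80)
            observed = t_ref * a0 ** (dT / 10)
            a_bis = refine_coefficient(t_ref, 70, observed, 70 - dT, bounds=(1.5, 6.0), tol=1e-13)
            a_cf = closed_form_coefficient(t_ref, 70, observed, 70 - dT)
            assert a_bis == pytest.approx(a_cf, rel=1e-9)

    def test_bounds_must_bracket(self):
        with pytest.raises(BracketingError):
            refine_coefficient(38.9, 70, 32.9 * MINUTES_PER_DAY, 8, bounds=(1.1, 1.5))


class TestTable:
    def test_size_criterion_table_matches_reported_days(self):
        model = VantHoffModel(A=3.91, T_ref_C=70, t_ref_min=37.0)
        table = shelf_life_table(model, [8, 25, 37])
        assert [round(d, 1) for d in table.days] == [120.6, 11.9, 2.3]
        assert round(float(table.months.iloc[0]), 1) == 4.0

    def test_empty_temperature_list_gives_empty_table(self):
        model = VantHoffModel(A=3.0, T_ref_C=70, t_ref_min=60.0)
        table = shelf_life_table(model, [])
        assert table.empty
        assert list(table.columns) == ["temperature_C", "minutes", "days", "months"]


class TestArrhenius:
    P_HOT = ArrheniusPoint.from_celsius(70, 0.3159)
    P_COLD = ArrheniusPoint.from_celsius(8, 0.1583)

    def test_two_point_activation_energy(self):
        ea = activation_energy(self.P_HOT, self.P_COLD)
        assert ea == pytest.approx(8.94e3, rel=0.005)

    def test_agrees_with_log_linear_slope_form(self):
        # independent form: E_A = -R * d(ln k) / d(1/T)
        slope = (math.log(self.P_HOT.k) - math.log(self.P_COLD.k)) / (
            1 / self.P_HOT.T_K - 1 / self.P_COLD.T_K
        )
        assert activation_energy(self.P_HOT, self.P_COLD) == pytest.approx(
            -R_GAS * slope, rel=1e-12
        )

    def test_equal_rates_give_zero_energy(self):
        p1 = ArrheniusPoint(T_K=343.15, k=0.2)
        p2 = ArrheniusPoint(T_K=281.15, k=0.2)
        assert activation_energy(p1, p2) == 0.0

    def test_symmetric_under_point_swap(self):
        assert activation_energy(self.P_HOT, self.P_COLD) == pytest.approx(
            activation_energy(self.P_COLD, self.P_HOT), rel=1e-12
        )

    def test_equal_temperatures_rejected(self):
        with pytest.raises(ValueError):
            activation_energy(self.P_HOT, ArrheniusPoint(T_K=343.15, k=0.1))

    def test_q10_of_zero_energy_is_one(self):
        assert q10_equivalent(0.0, 300.0) == 1.0

    def test_q10_inverts_its_defining_energy(self):
        T = 312.15
        ea = R_GAS * T**2 * math.log(2.5) / 10
        assert q10_equivalent(ea, T) == pytest.approx(2.5, rel=1e-12)

    def test_q10_of_measured_energy_is_mild(self):
        ea = activation_energy(self.P_HOT, self.P_COLD)
        assert q10_equivalent(ea, 312.15) == pytest.approx(1.12, abs=0.005)

    def test_validity_consistent_when_constructed_to_agree(self):
        ea = activation_energy(self.P_HOT, self.P_COLD)
        t_mid = 0.5 * (self.P_HOT.T_K + self.P_COLD.T_K)
        a = q10_equivalent(ea, t_mid)
        verdict = vant_hoff_validity(a, self.P_HOT, self.P_COLD, rtol=1e-6)
        assert verdict.verdict == "consistent"

    def test_validity_reports_disagreement_for_refined_coefficient(self):
        # the refined A = 3.15 implies ~93 kJ/mol while the rate pair gives
        # ~8.9 kJ/mol: both values are reported, verdict inconsistent
        verdict = vant_hoff_validity(3.15, self.P_HOT, self.P_COLD, rtol=0.5)
        assert verdict.verdict == "inconsistent"
        assert verdict.E_A_arrhenius == pytest.approx(8.94e3, rel=0.005)
        assert verdict.E_A_vant_hoff == pytest.approx(92.9e3, rel=0.005)

    def test_validity_with_infinite_tolerance_is_consistent(self):
        verdict = vant_hoff_validity(3.15, self.P_HOT, self.P_COLD, rtol=math.inf)
        assert verdict.verdict == "consistent"


class TestRateConstant:
    FIT = LinearFit(-0.0771, 12.0, 0.0, 1.0, 4, 0.0, 120.0)

    def test_fractional_rate(self):
        assert rate_constant_from_stage(self.FIT, 12.0) == pytest.approx(0.006425)

    def test_zero_slope_zero_rate(self):
        flat = LinearFit(0.0, 12.0, 0.0, 1.0, 4, 0.0, 120.0)
        assert rate_constant_from_stage(flat, 12.0) == 0.0

    def test_scale_invariance(self):
        doubled = LinearFit(-0.1542, 24.0, 0.0, 1.0, 4, 0.0, 120.0)
        assert rate_constant_from_stage(doubled, 24.0) == pytest.approx(
            rate_constant_from_stage(self.FIT, 12.0)
        )

    def test_zero_initial_rejected(self):
        with pytest.raises(ValueError):
            rate_constant_from_stage(self.FIT, 0.0)
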