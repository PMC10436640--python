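"""Markov cohort engine, transition parameters, CEA arithmetic and
one-way sensitivity analysis."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipc_eval import markov as mk

probs = st.floats(0.0, 1.0, allow_nan=False)
small_probs = st.floats(0.0, 0.5, allow_nan=False)

param_sets = st.builds(
    mk.MarkovParams,
    control_prob=probs,
    mort_poor=small_probs,
    mort_well=small_probs,
    relapse_prob=probs,
    transition_style=st.sampled_from(["relapse", "redistribute", "incremental"]),
    horizon=st.integers(1, 40),
)


class TestMortalityInputs:
    def test_attributable_fraction(self):
        # 1.8279 permille of 2.815 permille cardiovascular deaths
        assert round(100 * mk.attributable_fraction(), 2) == 64.93

    def test_pmh_product(self):
        # 0.2750 x 0.455 x (182.79/281.5) = 8.12%
        assert round(mk.hypertension_mortality(), 4) == 0.0812

    def test_zero_incidence_zero_mortality(self):
        inputs = mk.MortalityInputs(incidence=0.0)
        assert mk.hypertension_mortality(inputs) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            mk.hypertension_mortality(
                mk.MortalityInputs(cvd_death_rate_permille=0.0))
        with pytest.raises(ValueError):
            mk.hypertension_mortality(mk.MortalityInputs(
                hyp_death_rate_permille=3.0, cvd_death_rate_permille=2.0))


class TestTransitionMatrix:
    @given(param_sets)
    @settings(max_examples=100, deadline=None)
    def test_rows_stochastic_death_absorbing(self, params):
        m = mk.build_transition_matrix(params)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(m >= 0)
        np.testing.assert_array_equal(m[2], [0.0, 0.0, 1.0])

    def test_certain_control_no_death(self):
        params = mk.MarkovParams(control_prob=1.0, mort_poor=0.0,
                                 mort_well=0.0, relapse_prob=0.0)
        trace = mk.run_cohort(params)
        np.testing.assert_allclose(trace.fractions[1], [0.0, 1.0, 0.0])

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            mk.build_transition_matrix(mk.MarkovParams(control_prob=1.2))


class TestCohortTrace:
    def test_cycle_one_anchors(self):
        """First-cycle counts match the published cohort table for both
        arms: (78, 10, 8) without intervention, (25, 63, 8) with."""
        t_none = mk.run_cohort(mk.no_intervention_params())
        t_ipc = mk.run_cohort(mk.ipc_params())
        assert t_none.counts[1].tolist() == [78, 10, 8]
        assert t_ipc.counts[1].tolist() == [25, 63, 8]

    def test_early_cycle_anchors(self):
        t_none = mk.run_cohort(mk.no_intervention_params())
        t_ipc = mk.run_cohort(mk.ipc_params())
        assert t_none.counts[2].tolist() == [67, 15, 14]
        assert t_none.counts[3].tolist() == [59, 17, 20]
        assert t_ipc.counts[2].tolist() == [24, 62, 10]
        assert t_ipc.counts[3].tolist() == [23, 60, 13]

    def test_terminal_anchors(self):
        t_none = mk.run_cohort(mk.no_intervention_params())
        t_ipc = mk.run_cohort(mk.ipc_params())
        assert t_none.counts[28].tolist() == [12, 5, 79]
        assert t_ipc.counts[28].tolist() == [11, 30, 55]

    def test_zero_mortality_no_deaths(self):
        params = mk.MarkovParams(control_prob=0.5, mort_poor=0.0, mort_well=0.0)
        trace = mk.run_cohort(params)
        assert np.all(trace.counts[:, 2] == 0)

    @given(param_sets)
    @settings(max_examples=60, deadline=None)
    def test_trace_invariants(self, params):
        trace = mk.run_cohort(params)
        np.testing.assert_allclose(trace.fractions.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(trace.dead_fraction) >= -1e-15)
        assert np.all(trace.counts.sum(axis=1) == params.cohort_size)
        assert np.all(trace.counts >= 0)

    @given(param_sets)
    @settings(max_examples=40, deadline=None)
    def test_matches_matrix_power_oracle(self, params):
        """The iterated trace equals v0 M^t from the dense matrix power."""
        trace = mk.run_cohort(params)
        m = mk.build_transition_matrix(params)
        v0 = np.array([1.0, 0.0, 0.0])
        for t in (0, 1, params.horizon // 2, params.horizon):
            expected = v0 @ np.linalg.matrix_power(m, t)
            np.testing.assert_allclose(trace.fractions[t], expected, atol=1e-12)


class TestLifeYearsAndQaly:
    def test_zero_mortality_full_horizon(self):
        params = mk.MarkovParams(control_prob=0.3, mort_poor=0.0, mort_well=0.0)
        trace = mk.run_cohort(params)
        assert mk.life_years(trace, "end-of-cycle") == pytest.approx(28.0)
        assert mk.life_years(trace, "begin-of-cycle") == pytest.approx(28.0)
        assert mk.life_years(trace, "include-cycle-0") == pytest.approx(29.0)

    def test_calibrated_conventions_reproduce_survival(self):
        """Begin-of-cycle counting reproduces the published survival pair
        (13.22 without intervention, 18.62 with) and the 5.40 QALY gain."""
        cal = mk.calibrate_life_year_convention()
        assert cal["selected"] == "begin-of-cycle"
        t_none = mk.run_cohort(mk.no_intervention_params())
        t_ipc = mk.run_cohort(mk.ipc_params())
        assert mk.life_years(t_none) == pytest.approx(13.22, abs=0.02)
        assert mk.life_years(t_ipc) == pytest.approx(18.62, abs=0.02)
        assert mk.incremental_qaly(t_ipc, t_none) == pytest.approx(5.40, abs=0.02)

    def test_unit_utilities_qaly_equals_life_years(self):
        trace = mk.run_cohort(mk.ipc_params())
        assert mk.qaly(trace) == pytest.approx(mk.life_years(trace))

    def test_zero_utilities_zero_qaly(self):
        trace = mk.run_cohort(mk.ipc_params(u_poor=0.0, u_well=0.0))
        assert mk.qaly(trace) == 0.0

    def test_unknown_convention_rejected(self):
        trace = mk.run_cohort(mk.ipc_params())
        with pytest.raises(ValueError):
            mk.life_years(trace, "quarterly")

    @given(st.floats(0.0, 0.3), st.floats(0.0, 0.3))
    @settings(max_examples=30, deadline=None)
    def test_life_years_monotone_in_mortality(self, d_lo, d_hi):
        lo, hi = sorted([d_lo, d_hi])
        ly = lambda d: mk.life_years(mk.run_cohort(
            mk.MarkovParams(control_prob=0.5, mort_poor=d, mort_well=d / 2)))
        assert ly(hi) <= ly(lo) + 1e-12

    def test_life_years_monotone_in_control(self):
        # more control helps whenever the well state is safer
        lys = [mk.life_years(mk.run_cohort(mk.MarkovParams(control_prob=c)))
               for c in (0.1, 0.4, 0.7, 1.0)]
        assert all(a < b for a, b in zip(lys, lys[1:]))


class TestCostAndCer:
    def test_zero_cost(self):
        trace = mk.run_cohort(mk.ipc_params())
        rule = mk.CostRule(annual_cost_per_patient=0.0)
        assert mk.cumulative_cost(trace, rule) == 0.0

    def test_linearity_in_annual_cost(self):
        trace = mk.run_cohort(mk.ipc_params())
        one = mk.cumulative_cost(trace, mk.CostRule(annual_cost_per_patient=77.80))
        two = mk.cumulative_cost(trace, mk.CostRule(annual_cost_per_patient=155.60))
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_first_cycle_only_accrual(self):
        trace = mk.run_cohort(mk.ipc_params())
        rule = mk.CostRule(accrual_basis="first-cycle-only")
        assert mk.cumulative_cost(trace, rule) == pytest.approx(77.80)

    def test_published_cer_arithmetic(self):
        # ¥470.37 over 5.40 QALYs ~ ¥87.10 per QALY, far below WTP
        ratio = mk.cer(470.37, 5.40)
        assert ratio == pytest.approx(87.10, abs=0.01)
        assert mk.wtp_check(ratio)

    def test_zero_cost_zero_ratio(self):
        assert mk.cer(0.0, 5.40) == 0.0

    def test_wtp_boundary_inclusive(self):
        assert mk.wtp_check(mk.cer(57_700.0, 1.0))
        assert not mk.wtp_check(57_700.01)

    def test_nonpositive_incremental_rejected(self):
        with pytest.raises(ValueError, match="dominated|positive"):
            mk.cer(100.0, 0.0)

    def test_evaluate_cea_summary(self):
        res = mk.evaluate_cea()
        assert res.incremental_qaly > 0
        assert res.cer == pytest.approx(
            res.cumulative_cost / res.incremental_qaly)
        assert res.below_wtp
        assert dataclasses.asdict(res)  # JSON-serialisable summary


class TestSensitivity:
    def test_control_prob_plus_minus_ten_points(self):
        """±10 percentage points on the intervention arm's control
        probability move terminal deaths to 57 and 52."""
        rows = mk.one_way_sensitivity(
            mk.ipc_params(), "control_prob", [-0.10, +0.10], mode="absolute")
        assert rows[0]["deaths_at_horizon"] == 57
        assert rows[1]["deaths_at_horizon"] == 52

    def test_identity_at_zero_delta(self):
        base = mk.run_cohort(mk.ipc_params())
        row = mk.one_way_sensitivity(
            mk.ipc_params(), "control_prob", [0.0])[0]
        assert row["deaths_at_horizon"] == int(base.counts[-1, 2])
        assert row["life_years"] == pytest.approx(mk.life_years(base))

    def test_relative_mode(self):
        row = mk.one_way_sensitivity(
            mk.ipc_params(), "control_prob", [0.1], mode="relative")[0]
        assert row["value"] == pytest.approx(0.7188 * 1.1)

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            row = mk.one_way_sensitivity(
                mk.ipc_params(), "control_prob", [0.5], mode="absolute")[0]
        assert row["value"] == 1.0

    def test_cost_scaling(self):
        rows = mk.one_way_sensitivity(
            mk.ipc_params(), "annual_cost_per_patient", [-0.2, 0.2],
            mode="relative")
        assert rows[1]["cumulative_cost"] == pytest.approx(
            1.5 * rows[0]["cumulative_cost"])

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            mk.one_way_sensitivity(mk.ipc_params(), "horizon", [1])
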