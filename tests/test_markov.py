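"""Unit and property tests for the cohort state-transition engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsaidburden.markov import (
    DiscountSpec,
    HealthState,
    ModelValidationError,
    TransitionModel,
    accumulate_arm,
    discount_factor,
    incremental,
    probability_to_rate,
    rate_to_probability,
    run_cohort,
    validate_transition_model,
)
from nsaidburden.markov import ArmResult


def _alive_dead(p_death: float) -> TransitionModel:
    states = (
        HealthState("alive", utility=1.0, annual_cost=0.0),
        HealthState("dead", utility=0.0, annual_cost=0.0, is_absorbing=True),
    )
    matrix = np.array([[1 - p_death, p_death], [0.0, 1.0]])
    return TransitionModel(states=states, matrix=matrix)


class TestValidation:
    def test_identity_matrix_is_valid(self):
        model = _alive_dead(0.0)
        assert validate_transition_model(model) is model

    def test_row_sum_error_names_offending_row(self):
        model = _alive_dead(0.0)
        model.matrix = np.array([[0.7, 0.2], [0.0, 1.0]])
        with pytest.raises(ModelValidationError, match="row 0"):
            validate_transition_model(model)

    def test_absorbing_state_with_leakage_rejected(self):
        model = _alive_dead(0.0)
        model.matrix = np.array([[1.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ModelValidationError, match="absorbing"):
            validate_transition_model(model)

    def test_entries_outside_unit_interval_rejected(self):
        model = _alive_dead(0.0)
        model.matrix = np.array([[1.5, -0.5], [0.0, 1.0]])
        with pytest.raises(ModelValidationError, match="outside"):
            validate_transition_model(model)

    def test_state_invariants(self):
        with pytest.raises(ModelValidationError):
            HealthState("bad", utility=1.2, annual_cost=0.0)
        with pytest.raises(ModelValidationError):
            HealthState("bad", utility=0.5, annual_cost=-1.0)
        with pytest.raises(ModelValidationError):
            HealthState("dead", utility=0.3, annual_cost=0.0, is_absorbing=True)


class TestDiscounting:
    @pytest.mark.parametrize(
        "rate,cycle,expected",
        [
            (0.035, 0, 1.0),
            (0.0, 7, 1.0),
            (0.035, 1, 1 / 1.035),
        ],
    )
    def test_discount_factor(self, rate, cycle, expected):
        spec = DiscountSpec(annual_rate=rate)
        assert discount_factor(spec, cycle, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_disabled_discounting_is_identity(self):
        spec = DiscountSpec(annual_rate=0.035, enabled=False)
        assert discount_factor(spec, 5, 1.0) == 1.0


class TestCohortTrace:
    def test_identity_matrix_keeps_occupancy_constant(self):
        trace = run_cohort(_alive_dead(0.0), [0.6, 0.4], 10)
        assert np.allclose(trace.occupancy, [0.6, 0.4])

    def test_constant_death_probability_hand_calculation(self):
        trace = run_cohort(_alive_dead(0.5), [1.0, 0.0], 2)
        assert trace.occupancy[2, 0] == pytest.approx(0.25)
        assert trace.occupancy.shape == (3, 2)

    def test_zero_death_probability_keeps_dead_empty(self):
        trace = run_cohort(_alive_dead(0.0), [1.0, 0.0], 10)
        assert np.all(trace.occupancy[:, 1] == 0.0)

    def test_horizon_must_sit_on_cycle_grid(self):
        with pytest.raises(ModelValidationError, match="multiple"):
            run_cohort(_alive_dead(0.1), [1.0, 0.0], 2.5)

    def test_death_occupancy_is_non_decreasing(self):
        trace = run_cohort(_alive_dead(0.3), [1.0, 0.0], 20)
        assert np.all(np.diff(trace.occupancy[:, 1]) >= -1e-12)


class TestAccumulation:
    @pytest.mark.parametrize("utility,expected", [(1.0, 10.0), (0.5, 5.0)])
    def test_undiscounted_single_state_totals(self, utility, expected):
        states = (HealthState("alive", utility=utility, annual_cost=100.0),)
        model = TransitionModel(states=states, matrix=np.array([[1.0]]))
        trace = run_cohort(model, [1.0], 10)
        res = accumulate_arm(trace, states, DiscountSpec(annual_rate=0.0))
        assert res.total_discounted_qalys == pytest.approx(expected)
        assert res.total_discounted_cost == pytest.approx(1000.0)

    def test_discounted_single_state_matches_geometric_series(self):
        states = (HealthState("alive", utility=1.0, annual_cost=0.0),)
        model = TransitionModel(states=states, matrix=np.array([[1.0]]))
        trace = run_cohort(model, [1.0], 10)
        res = accumulate_arm(trace, states, DiscountSpec(annual_rate=0.035))
        expected = sum(1.035 ** (-k) for k in range(1, 11))
        assert res.total_discounted_qalys == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(8.3166, abs=5e-4)

    def test_alive_dead_closed_form_oracle(self):
        # engine QALYs equal u * sum_k (1-p)^k for constant death risk
        p, u, n = 0.2, 0.7, 15
        states = (
            HealthState("alive", utility=u, annual_cost=0.0),
            HealthState("dead", utility=0.0, annual_cost=0.0, is_absorbing=True),
        )
        model = TransitionModel(states=states, matrix=np.array([[1 - p, p], [0, 1]]))
        trace = run_cohort(model, [1.0, 0.0], n)
        res = accumulate_arm(trace, states, DiscountSpec(annual_rate=0.0))
        closed_form = u * sum((1 - p) ** k for k in range(1, n + 1))
        assert res.total_discounted_qalys == pytest.approx(closed_form, abs=1e-9)

    def test_half_cycle_correction_averages_adjacent_cycles(self):
        p = 0.5
        states = (
            HealthState("alive", utility=1.0, annual_cost=0.0),
            HealthState("dead", utility=0.0, annual_cost=0.0, is_absorbing=True),
        )
        model = TransitionModel(states=states, matrix=np.array([[1 - p, p], [0, 1]]))
        trace = run_cohort(model, [1.0, 0.0], 2)
        res = accumulate_arm(
            trace, states, DiscountSpec(annual_rate=0.0), half_cycle_correction=True
        )
        assert res.total_discounted_qalys == pytest.approx(0.75 + 0.375)
        assert res.metadata["half_cycle_correction"] is True

    def test_utility_scaling_scales_qalys_linearly(self):
        p = 0.1
        for scale in (0.5, 2 / 3):
            base_states = (
                HealthState("alive", utility=0.9, annual_cost=200.0),
                HealthState("dead", utility=0.0, annual_cost=0.0, is_absorbing=True),
            )
            scaled_states = (
                HealthState("alive", utility=0.9 * scale, annual_cost=200.0 * scale),
                HealthState("dead", utility=0.0, annual_cost=0.0, is_absorbing=True),
            )
            matrix = np.array([[1 - p, p], [0, 1]])
            model = TransitionModel(states=base_states, matrix=matrix)
            trace = run_cohort(model, [1.0, 0.0], 10)
            disc = DiscountSpec(annual_rate=0.035)
            base = accumulate_arm(trace, base_states, disc)
            scaled = accumulate_arm(trace, scaled_states, disc)
            assert scaled.total_discounted_qalys == pytest.approx(
                base.total_discounted_qalys * scale
            )
            assert scaled.total_discounted_cost == pytest.approx(
                base.total_discounted_cost * scale
            )


class TestIncrement:
    def test_published_cost_increment(self):
        hpe = ArmResult(4.812, 2526.0, {})
        comp = ArmResult(4.904, 1429.0, {})
        assert incremental(hpe, comp).delta_cost == pytest.approx(1097.0)

    def test_published_qaly_increment(self):
        hpe = ArmResult(4.523, 50_215.0, {})
        comp = ArmResult(4.634, 50_008.0, {})
        assert incremental(hpe, comp).delta_qalys == pytest.approx(-0.111)

    def test_identical_arms_give_zero_deltas(self):
        arm = ArmResult(3.0, 100.0, {})
        inc = incremental(arm, arm)
        assert inc.delta_qalys == 0.0 and inc.delta_cost == 0.0


class TestRateConversion:
    def test_zero_rate_gives_zero_probability(self):
        assert rate_to_probability(0.0) == 0.0

    def test_large_rate_approaches_one(self):
        assert rate_to_probability(1e9) == pytest.approx(1.0)

    def test_closed_form_example(self):
        assert rate_to_probability(0.1, 1.0) == pytest.approx(0.09516, abs=5e-6)

    @settings(deadline=None, max_examples=50)
    @given(
        rate=st.floats(0.0, 5.0, allow_nan=False),
        cl=st.sampled_from([0.25, 0.5, 1.0, 2.0]),
    )
    def test_rate_probability_round_trip(self, rate, cl):
        p = rate_to_probability(rate, cl)
        assert probability_to_rate(p, cl) == pytest.approx(rate, abs=1e-9)
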