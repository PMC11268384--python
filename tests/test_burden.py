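"""Prevalence rates, national scaling, burden totals, excess events."""

import numpy as np
import pytest

from nsaidburden.burden import (
    BurdenTable,
    NationalCount,
    PopulationSpec,
    PrevalenceRecord,
    excess_events,
    national_burden,
    overlap_adjustment,
    rate_per_1000,
    round_half_up,
    scale_to_population,
    share_of_total,
)
from nsaidburden.datasets import NATIONAL_COMPONENTS, SAMPLE_DENOMINATOR
from nsaidburden.markov import ArmResult
from nsaidburden.models import run_pair


def _record(affected, at_risk=None, denom=SAMPLE_DENOMINATOR, name="x"):
    return PrevalenceRecord(
        indication=name,
        n_at_risk=at_risk if at_risk is not None else max(affected * 10, 1),
        n_affected=affected,
        denominator=denom,
    )


class TestRates:
    def test_zero_numerator_gives_zero_rate(self):
        r = rate_per_1000(_record(0, at_risk=10))
        assert r.rate == 0.0

    def test_record_ordering_invariant_enforced(self):
        with pytest.raises(ValueError, match="affected"):
            PrevalenceRecord("x", n_at_risk=5, n_affected=10, denominator=100)

    def test_wilson_interval_available_behind_flag(self):
        rec = _record(1188, at_risk=83_104)
        wald = rate_per_1000(rec, ci_method="wald")
        wilson = rate_per_1000(rec, ci_method="wilson")
        assert wald.lower != wilson.lower
        assert wilson.lower > 0


class TestScaling:
    def test_zero_numerator_scales_to_zero(self):
        nc = scale_to_population(_record(0, at_risk=10), PopulationSpec())
        assert nc.count == 0

    def test_scaling_linearity_in_population(self):
        rec = _record(2733, at_risk=136_749)
        pop1 = PopulationSpec(n_registered=30_000_000)
        pop2 = PopulationSpec(n_registered=60_000_000)
        a, b = scale_to_population(rec, pop1), scale_to_population(rec, pop2)
        # compare before integer rounding: exact proportions double
        assert b.count == pytest.approx(2 * a.count, abs=1)
        assert b.upper == pytest.approx(2 * a.upper, abs=1)

    def test_rounding_is_half_up(self):
        assert round_half_up(0.5) == 1
        assert round_half_up(1.5) == 2
        assert round_half_up(-0.5) == -1
        assert round_half_up(1.675, 2) == 1.68


class TestShares:
    def test_single_indication_gets_everything(self):
        assert share_of_total({"a": 42})["a"] == 100.0

    def test_equal_counts_split_evenly(self):
        shares = share_of_total({k: 7 for k in "abcde"})
        assert all(v == pytest.approx(20.0) for v in shares.values())

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            share_of_total({"a": 0})


class TestNationalBurden:
    def test_totals_are_exact_sums_per_sample(self, draws):
        counts = {k: 10_000 for k in draws.models}
        table = national_burden(counts, draws)
        manual_q = sum(10_000 * m.delta_qalys for m in draws.models.values())
        assert np.array_equal(table.qaly_samples, manual_q)
        row_sum = sum(r.qaly_total.mean for r in table.rows.values())
        assert table.total_qalys.mean == pytest.approx(row_sum, rel=1e-12)

    def test_zero_increments_give_zero_totals(self, draws):
        counts = {k: 0 for k in draws.models}
        table = national_burden(counts, draws)
        assert table.total_qalys.mean == 0.0
        assert table.total_cost_millions.upper == 0.0

    def test_missing_indication_rejected(self, draws):
        counts = {k: 1 for k in draws.models}
        counts.pop("heart_failure")
        with pytest.raises(KeyError, match="heart_failure"):
            national_burden(counts, draws)

    def test_point_component_table_sums_published_values(self):
        table = BurdenTable.from_point_components(
            {k: v[0] for k, v in NATIONAL_COMPONENTS.items()},
            {k: v[1] for k, v in NATIONAL_COMPONENTS.items()},
        )
        assert table.total_qalys.mean == pytest.approx(6335.0)
        assert table.total_cost_millions.mean == pytest.approx(31.43)


class TestExcessEvents:
    def test_identical_arms_give_zero_excess(self):
        arm = ArmResult(1.0, 1.0, {"death": 0.2, "stroke": 0.05})
        assert all(v == 0.0 for v in excess_events(arm, arm, 5000).values())

    def test_known_incidence_gap_arithmetic(self):
        hpe = ArmResult(1.0, 1.0, {"death": 0.21})
        comp = ArmResult(1.0, 1.0, {"death": 0.20})
        assert excess_events(hpe, comp, 1000)["death"] == pytest.approx(10.0)

    def test_matches_direct_trace_differencing(self, models, engine):
        """End-to-end excess counts equal brute-force trace subtraction."""
        from nsaidburden.markov import run_cohort
        from nsaidburden.models import initial_occupancy

        spec = models["chronic_kidney_disease"]
        count = 15_799
        pair = run_pair(spec, engine)
        got = excess_events(pair.hpe, pair.comparator, count)

        init = initial_occupancy(spec)
        t_h = run_cohort(spec.hpe_arm, init, engine.horizon_years)
        t_c = run_cohort(spec.comparator_arm, init, engine.horizon_years)
        for event in ("aki_hospital", "death"):
            j = spec.hpe_arm.index(event)
            brute = (t_h.entries[1:, j].sum() - t_c.entries[1:, j].sum()) * count
            assert got[event] == pytest.approx(brute, abs=1e-6)


class TestOverlapAdjustment:
    def test_at_risk_deduction_arithmetic(self, prevalence):
        adjusted = overlap_adjustment(prevalence)
        older = adjusted["older_no_gpa"]
        assert older.n_at_risk == 1_355_707 - (245_778 + 87_804 + 136_749)
        assert older.n_at_risk == 885_376
        # affected falls proportionally to the at-risk reduction
        factor = 885_376 / 1_355_707
        assert older.n_affected == round_half_up(18_591 * factor)
        assert adjusted["heart_failure"] == prevalence["heart_failure"]

    def test_zero_count_deductions_leave_records_unchanged(self):
        records = {
            "older_no_gpa": _record(100, at_risk=1000, name="older_no_gpa"),
            "oral_anticoagulant": _record(0, at_risk=0, name="oral_anticoagulant"),
            "heart_failure": _record(0, at_risk=0, name="heart_failure"),
            "chronic_kidney_disease": _record(0, at_risk=0, name="chronic_kidney_disease"),
        }
        adjusted = overlap_adjustment(records)
        assert adjusted["older_no_gpa"] == records["older_no_gpa"]

    def test_excessive_deduction_rejected(self):
        records = {
            "older_no_gpa": _record(10, at_risk=100, name="older_no_gpa"),
            "oral_anticoagulant": _record(50, at_risk=500, name="oral_anticoagulant"),
            "heart_failure": _record(0, at_risk=0, name="heart_failure"),
            "chronic_kidney_disease": _record(0, at_risk=0, name="chronic_kidney_disease"),
        }
        with pytest.raises(ValueError, match="exceed"):
            overlap_adjustment(records)

    def test_missing_record_rejected(self, prevalence):
        partial = {k: v for k, v in prevalence.items() if k != "heart_failure"}
        with pytest.raises(KeyError, match="heart_failure"):
            overlap_adjustment(partial)
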