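"""Structure and behaviour of the five indication model pairs."""

import numpy as np
import pytest

from nsaidburden.config import EngineConfig
from nsaidburden.markov import probability_to_rate
from nsaidburden.models import (
    BASE_CASE_MIX,
    INDICATIONS,
    STRUCTURES,
    WEIGHTED_AVERAGE_MIX,
    ExposureRule,
    NsaidMix,
    apply_exposure_rule,
    apply_nsaid_mix,
    build_model,
    run_pair,
)
from nsaidburden.parameters import MissingParameterError, point_values


class TestTopology:
    """State graphs must match the indication-specific adverse events."""

    def test_stroke_state_only_in_anticoagulant_model(self):
        for indication in INDICATIONS:
            names = STRUCTURES[indication].state_names()
            assert ("stroke" in names) == (indication == "oral_anticoagulant")

    def test_kidney_states_only_in_ckd_model(self):
        for indication in INDICATIONS:
            names = STRUCTURES[indication].state_names()
            has_renal = {"aki_primary_care", "aki_hospital", "ckd_progressed"} <= set(names)
            assert has_renal == (indication == "chronic_kidney_disease")

    def test_heart_failure_states(self):
        names = set(STRUCTURES["heart_failure"].state_names())
        assert {"well", "minor_exacerbation", "major_exacerbation", "death"} <= names
        assert not names & {"stroke", "serious_gi_event", "aki_hospital"}

    def test_gi_models_share_event_states(self):
        for indication in ("older_no_gpa", "peptic_ulcer_no_gpa", "oral_anticoagulant"):
            names = set(STRUCTURES[indication].state_names())
            assert {
                "gi_discomfort",
                "symptomatic_ulcer",
                "serious_gi_event",
                "death",
            } <= names

    def test_both_arms_share_the_state_set(self, pset):
        for indication in INDICATIONS:
            spec = build_model(indication, pset.tables[indication])
            assert spec.hpe_arm.state_names == spec.comparator_arm.state_names

    def test_ckd_model_has_post_aki_progression_pathway(self):
        structure = STRUCTURES["chronic_kidney_disease"]
        targets = {
            (t.source, t.target) for t in structure.transitions
        }
        assert ("aki_hospital", "ckd_progressed") in targets
        assert ("reduced_kidney_function", "ckd_progressed") in targets


class TestBuild:
    def test_missing_parameter_error_names_it(self, pset):
        table = dict(pset.tables["heart_failure"])
        del table["u_minor_exacerbation"]
        with pytest.raises(MissingParameterError, match="u_minor_exacerbation"):
            build_model("heart_failure", table)

    def test_unknown_indication_rejected(self, pset):
        with pytest.raises(KeyError, match="unknown indication"):
            build_model("aspirin_monotherapy", pset.tables["older_no_gpa"])

    def test_hpe_arm_event_probabilities_dominate_comparator(self, models):
        """The hazardous event is harmful by construction in every model."""
        for spec in models.values():
            i = spec.hpe_arm.index("well")
            hpe_row = spec.hpe_arm.matrix[i]
            comp_row = spec.comparator_arm.matrix[i]
            for t in spec.structure.transitions:
                if t.source == "well" and t.by_arm:
                    j = spec.hpe_arm.index(t.target)
                    assert hpe_row[j] >= comp_row[j] - 1e-12

    @pytest.mark.parametrize("preset,seed", [("paper_magnitude", 3), ("default", 4)])
    def test_all_increments_are_qaly_losses(self, preset, seed):
        from nsaidburden.synthetic import generate_parameter_tables

        pset = generate_parameter_tables(seed=seed, preset=preset)
        for dq, _dc in pset.ground_truth.values():
            assert dq < 0


class TestExposureRule:
    def test_full_horizon_exposure_equals_unrestricted_run(self, models, engine):
        spec = models["oral_anticoagulant"]
        limited = apply_exposure_rule(spec, ExposureRule(duration_years=10.0))
        assert run_pair(limited, engine).increment == run_pair(spec, engine).increment

    def test_harm_grows_with_exposure_duration(self, models, engine):
        for spec in models.values():
            d5 = run_pair(
                apply_exposure_rule(spec, ExposureRule(5.0)), engine
            ).increment.delta_qalys
            d10 = run_pair(
                apply_exposure_rule(spec, ExposureRule(10.0)), engine
            ).increment.delta_qalys
            assert abs(d5) <= abs(d10) + 1e-12

    def test_short_exposure_limits_harm(self, pset):
        engine = EngineConfig(cycle_length_years=0.25)
        spec = build_model(
            "older_no_gpa", pset.tables["older_no_gpa"], cycle_length=0.25
        )
        full = run_pair(spec, engine).increment.delta_qalys
        brief = run_pair(
            apply_exposure_rule(spec, ExposureRule(0.25)), engine
        ).increment.delta_qalys
        assert abs(brief) < 0.2 * abs(full)

    def test_duration_off_the_cycle_grid_rejected(self, models):
        with pytest.raises(Exception, match="cycle grid"):
            apply_exposure_rule(models["heart_failure"], ExposureRule(2.5))

    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError):
            ExposureRule(duration_years=0.0)


class TestNsaidMix:
    def test_base_case_mix_is_identity(self, models):
        spec = models["chronic_kidney_disease"]
        remixed = apply_nsaid_mix(spec, BASE_CASE_MIX)
        assert np.allclose(remixed.hpe_arm.matrix, spec.hpe_arm.matrix)
        assert np.allclose(remixed.comparator_arm.matrix, spec.comparator_arm.matrix)

    def test_uniform_relative_risk_scales_event_rates(self, models):
        r = 1.3
        mix = NsaidMix(
            weights={"naproxen": 1.0},
            relative_risks={
                cls: {"naproxen": r}
                for cls in ("gastrointestinal", "cardiovascular", "renal")
            },
        )
        spec = models["heart_failure"]
        remixed = apply_nsaid_mix(spec, mix)
        i = spec.hpe_arm.index("well")
        j = spec.hpe_arm.index("major_exacerbation")
        rate_base = probability_to_rate(spec.hpe_arm.matrix[i, j])
        rate_mixed = probability_to_rate(remixed.hpe_arm.matrix[i, j])
        assert rate_mixed == pytest.approx(r * rate_base, rel=1e-9)

    def test_weighted_mix_matches_hand_computed_rate(self, models):
        mix = NsaidMix(
            weights={"naproxen": 0.6, "ibuprofen": 0.4},
            relative_risks={"gastrointestinal": {"naproxen": 1.0, "ibuprofen": 0.5}},
        )
        factor = 0.6 * 1.0 + 0.4 * 0.5
        spec = models["older_no_gpa"]
        remixed = apply_nsaid_mix(spec, mix)
        i = spec.hpe_arm.index("well")
        j = spec.hpe_arm.index("serious_gi_event")
        assert probability_to_rate(remixed.hpe_arm.matrix[i, j]) == pytest.approx(
            factor * probability_to_rate(spec.hpe_arm.matrix[i, j]), rel=1e-9
        )

    def test_comparator_arm_untouched_by_mix(self, models):
        spec = models["older_no_gpa"]
        remixed = apply_nsaid_mix(spec, WEIGHTED_AVERAGE_MIX)
        assert np.allclose(remixed.comparator_arm.matrix, spec.comparator_arm.matrix)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            NsaidMix(weights={"naproxen": 0.7}, relative_risks={})

    def test_relative_risks_must_be_positive(self):
        with pytest.raises(ValueError, match="> 0"):
            NsaidMix(
                weights={"naproxen": 1.0},
                relative_risks={"renal": {"naproxen": -1.0}},
            )
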