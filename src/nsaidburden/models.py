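"""The five NSAID hazardous-prescribing indication models.

Each indication pairs two cohort state-transition models sharing one state
set: an HPE arm (the hazardous prescribing continues) and a comparator arm
(the counterfactual — NSAID plus gastroprotection for the two
gastrointestinal-risk indications, paracetamol instead of an NSAID for the
anticoagulant, heart-failure and chronic-kidney-disease indications).

Arm-dependent adverse-event transitions are parameterised as a
comparator-level annual probability plus a non-negative NSAID-attributable
excess (`<name>` and `<name>_excess`); the two combine on the rate scale.
This makes the HPE arm at least as risky as the comparator in every valid
parameter set and every probabilistic draw, so the hazardous event is
harmful by construction.

Cessation of hazardous prescribing after an adverse event is structural:
adverse-event states are one-cycle tunnels that drain into post-event
states (or a ceased-exposure "well" state) whose onward transitions use
comparator-level parameters.  Cohort mass never returns to the exposed
state, so no separate exposed/unexposed bookkeeping is needed.  Limited
exposure duration (review and cessation without an event) is handled by
switching the never-event occupancy to comparator transition probabilities
once the duration has elapsed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import EngineConfig
from .markov import (
    ArmResult,
    CohortTrace,
    DiscountSpec,
    HealthState,
    IncrementalResult,
    ModelValidationError,
    TransitionModel,
    accumulate_arm,
    incremental,
    probability_to_rate,
    rate_to_probability,
    rescale_probability,
    run_cohort_piecewise,
    validate_transition_model,
)
from .parameters import MissingParameterError, ParameterSpec, point_values

INDICATIONS = (
    "older_no_gpa",
    "peptic_ulcer_no_gpa",
    "oral_anticoagulant",
    "heart_failure",
    "chronic_kidney_disease",
)

INDICATION_LABELS = {
    "older_no_gpa": "NSAID in older people without gastroprotection",
    "peptic_ulcer_no_gpa": "NSAID with previous peptic ulcer without gastroprotection",
    "oral_anticoagulant": "NSAID with oral anticoagulant",
    "heart_failure": "NSAID with heart failure",
    "chronic_kidney_disease": "NSAID with chronic kidney disease",
}

NSAID_DRUGS = ("celecoxib", "diclofenac", "ibuprofen", "naproxen")


class RowOverflowError(ModelValidationError):
    """Sampled transition probabilities from one state exceed 1."""

    def __init__(self, indication: str, state: str, total: float):
        self.indication = indication
        self.state = state
        super().__init__(
            f"{indication}: transitions out of '{state}' sum to {total:.6f} > 1"
        )


@dataclass(frozen=True)
class StateDef:
    """Structural description of a health state within one indication."""

    name: str
    acute: bool = False
    absorbing: bool = False
    utility_param: str | None = None
    cost_param: str | None = None

    def u_param(self) -> str:
        return self.utility_param or f"u_{self.name}"

    def c_param(self) -> str:
        return self.cost_param or f"c_{self.name}"


@dataclass(frozen=True)
class TransitionDef:
    """One directed transition, named by the parameter that drives it.

    ``by_arm`` transitions take the comparator-level probability ``param``
    in the comparator arm and combine it with ``param + '_excess'`` in the
    HPE arm.  ``event_class`` tags the NSAID-attributable transitions for
    the weighted-NSAID-mix sensitivity analysis.
    """

    source: str
    target: str
    param: str
    by_arm: bool = False
    event_class: str | None = None


@dataclass(frozen=True)
class ModelStructure:
    indication: str
    states: tuple[StateDef, ...]
    transitions: tuple[TransitionDef, ...]
    default_target: Mapping[str, str]  # residual-mass destination per tunnel state
    cohort_profile: Mapping[str, object]

    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    def required_parameters(self) -> tuple[str, ...]:
        names: list[str] = []
        for t in self.transitions:
            names.append(t.param)
            if t.by_arm:
                names.append(t.param + "_excess")
        for s in self.states:
            if not s.absorbing:
                names.extend([s.u_param(), s.c_param()])
        seen: dict[str, None] = {}
        for n in names:
            seen.setdefault(n)
        return tuple(seen)


def _gi_structure(indication: str, with_stroke: bool, profile: dict) -> ModelStructure:
    states = [
        StateDef("well"),
        StateDef("gi_discomfort", acute=True),
        StateDef("symptomatic_ulcer", acute=True),
        StateDef("serious_gi_event", acute=True),
        StateDef("post_gi_event"),
    ]
    if with_stroke:
        states += [StateDef("stroke", acute=True), StateDef("post_stroke")]
    states += [
        StateDef("well_ceased", utility_param="u_well", cost_param="c_well"),
        StateDef("death", absorbing=True),
    ]
    transitions = [
        TransitionDef("well", "gi_discomfort", "p_gi_discomfort", True, "gastrointestinal"),
        TransitionDef("well", "symptomatic_ulcer", "p_symptomatic_ulcer", True, "gastrointestinal"),
        TransitionDef("well", "serious_gi_event", "p_serious_gi", True, "gastrointestinal"),
        TransitionDef("well", "death", "p_death_background"),
        TransitionDef("gi_discomfort", "well_ceased", "p_discomfort_resolve"),
        TransitionDef("gi_discomfort", "symptomatic_ulcer", "p_discomfort_to_ulcer"),
        TransitionDef("gi_discomfort", "death", "p_death_background"),
        TransitionDef("symptomatic_ulcer", "serious_gi_event", "p_ulcer_to_bleed"),
        TransitionDef("symptomatic_ulcer", "well_ceased", "p_ulcer_heal"),
        TransitionDef("symptomatic_ulcer", "death", "p_death_background"),
        TransitionDef("serious_gi_event", "death", "p_gi_event_mortality"),
        TransitionDef("post_gi_event", "serious_gi_event", "p_rebleed"),
        TransitionDef("post_gi_event", "death", "p_death_post_gi"),
        TransitionDef("well_ceased", "gi_discomfort", "p_gi_discomfort"),
        TransitionDef("well_ceased", "symptomatic_ulcer", "p_symptomatic_ulcer"),
        TransitionDef("well_ceased", "serious_gi_event", "p_serious_gi"),
        TransitionDef("well_ceased", "death", "p_death_background"),
    ]
    default_target = {"serious_gi_event": "post_gi_event"}
    if with_stroke:
        transitions += [
            TransitionDef("well", "stroke", "p_stroke", True, "cardiovascular"),
            TransitionDef("stroke", "death", "p_stroke_mortality"),
            TransitionDef("post_stroke", "death", "p_death_post_stroke"),
            TransitionDef("well_ceased", "stroke", "p_stroke"),
        ]
        default_target["stroke"] = "post_stroke"
    return ModelStructure(
        indication=indication,
        states=tuple(states),
        transitions=tuple(transitions),
        default_target=default_target,
        cohort_profile=profile,
    )


def _hf_structure() -> ModelStructure:
    states = (
        StateDef("well"),
        StateDef("minor_exacerbation", acute=True),
        StateDef("major_exacerbation", acute=True),
        StateDef("well_ceased", utility_param="u_well", cost_param="c_well"),
        StateDef("death", absorbing=True),
    )
    transitions = (
        TransitionDef("well", "minor_exacerbation", "p_minor_exacerbation", True, "cardiovascular"),
        TransitionDef("well", "major_exacerbation", "p_major_exacerbation", True, "cardiovascular"),
        TransitionDef("well", "death", "p_death_background"),
        TransitionDef("minor_exacerbation", "major_exacerbation", "p_minor_to_major"),
        TransitionDef("minor_exacerbation", "death", "p_death_background"),
        TransitionDef("major_exacerbation", "death", "p_major_mortality"),
        TransitionDef("well_ceased", "minor_exacerbation", "p_minor_exacerbation"),
        TransitionDef("well_ceased", "major_exacerbation", "p_major_exacerbation"),
        TransitionDef("well_ceased", "death", "p_death_background"),
    )
    return ModelStructure(
        indication="heart_failure",
        states=states,
        transitions=transitions,
        default_target={
            "minor_exacerbation": "well_ceased",
            "major_exacerbation": "well_ceased",
        },
        cohort_profile={"mean_age": 74, "female": 0.45, "diagnosis": "heart failure"},
    )


def _ckd_structure() -> ModelStructure:
    states = (
        StateDef("well"),
        StateDef("aki_primary_care", acute=True),
        StateDef("aki_hospital", acute=True),
        StateDef("reduced_kidney_function"),
        StateDef("ckd_progressed"),
        StateDef("well_ceased", utility_param="u_well", cost_param="c_well"),
        StateDef("death", absorbing=True),
    )
    transitions = (
        TransitionDef("well", "aki_primary_care", "p_aki_primary", True, "renal"),
        TransitionDef("well", "aki_hospital", "p_aki_hospital", True, "renal"),
        TransitionDef("well", "ckd_progressed", "p_ckd_progression"),
        TransitionDef("well", "death", "p_death_background"),
        TransitionDef("aki_primary_care", "reduced_kidney_function", "p_aki_residual"),
        TransitionDef("aki_primary_care", "death", "p_aki_primary_mortality"),
        TransitionDef("aki_hospital", "death", "p_aki_hospital_mortality"),
        TransitionDef("aki_hospital", "reduced_kidney_function", "p_aki_hospital_residual"),
        TransitionDef("aki_hospital", "ckd_progressed", "p_aki_hospital_progression"),
        TransitionDef("reduced_kidney_function", "ckd_progressed", "p_reduced_to_progressed"),
        TransitionDef("reduced_kidney_function", "death", "p_death_reduced"),
        TransitionDef("ckd_progressed", "death", "p_death_progressed"),
        TransitionDef("well_ceased", "aki_primary_care", "p_aki_primary"),
        TransitionDef("well_ceased", "aki_hospital", "p_aki_hospital"),
        TransitionDef("well_ceased", "ckd_progressed", "p_ckd_progression"),
        TransitionDef("well_ceased", "death", "p_death_background"),
    )
    return ModelStructure(
        indication="chronic_kidney_disease",
        states=states,
        transitions=transitions,
        default_target={
            "aki_primary_care": "well_ceased",
            "aki_hospital": "well_ceased",
        },
        cohort_profile={
            "mean_age": 72,
            "female": 0.50,
            "diagnosis": "CKD, eGFR < 45 mL/min",
        },
    )


STRUCTURES: dict[str, ModelStructure] = {
    "older_no_gpa": _gi_structure(
        "older_no_gpa",
        with_stroke=False,
        profile={"mean_age": 72, "female": 0.55, "diagnosis": "age >= 65, no gastroprotection"},
    ),
    "peptic_ulcer_no_gpa": _gi_structure(
        "peptic_ulcer_no_gpa",
        with_stroke=False,
        profile={"mean_age": 62, "female": 0.45, "diagnosis": "previous peptic ulcer"},
    ),
    "oral_anticoagulant": _gi_structure(
        "oral_anticoagulant",
        with_stroke=True,
        profile={"mean_age": 74, "female": 0.48, "diagnosis": "concurrent oral anticoagulant"},
    ),
    "heart_failure": _hf_structure(),
    "chronic_kidney_disease": _ckd_structure(),
}


@dataclass(frozen=True)
class ExposureRule:
    """How long the hazardous prescribing continues without an event."""

    duration_years: float
    cessation_on_event: bool = True

    def __post_init__(self):
        if self.duration_years <= 0:
            raise ValueError("exposure duration must be positive")


@dataclass(frozen=True)
class NsaidMix:
    """Weighted NSAID mix with per-drug relative risks by adverse-event class.

    The base case is 100% naproxen with all relative risks 1.  ``weights``
    must sum to 1; ``relative_risks`` maps an event class
    (``gastrointestinal`` | ``cardiovascular`` | ``renal``) to per-drug
    relative risks versus naproxen.
    """

    weights: Mapping[str, float]
    relative_risks: Mapping[str, Mapping[str, float]]

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"NSAID mix weights sum to {total!r}, not 1")
        for cls, rrs in self.relative_risks.items():
            for drug, rr in rrs.items():
                if rr <= 0:
                    raise ValueError(f"relative risk {cls}/{drug} must be > 0")

    def rate_factor(self, event_class: str) -> float:
        rrs = self.relative_risks.get(event_class, {})
        return sum(w * rrs.get(drug, 1.0) for drug, w in self.weights.items())


BASE_CASE_MIX = NsaidMix(weights={"naproxen": 1.0}, relative_risks={})

#: England community prescribing mix (2022: naproxen ~69% of oral NSAID items)
#: with class relative risks vs naproxen from the comparative-safety
#: literature (COX-2 selectivity lowers GI risk; diclofenac and ibuprofen
#: carry higher cardiovascular/renal risk than naproxen).
WEIGHTED_AVERAGE_MIX = NsaidMix(
    weights={"naproxen": 0.69, "ibuprofen": 0.20, "diclofenac": 0.06, "celecoxib": 0.05},
    relative_risks={
        "gastrointestinal": {"naproxen": 1.0, "ibuprofen": 0.8, "diclofenac": 0.9, "celecoxib": 0.45},
        "cardiovascular": {"naproxen": 1.0, "ibuprofen": 1.2, "diclofenac": 1.4, "celecoxib": 1.25},
        "renal": {"naproxen": 1.0, "ibuprofen": 1.1, "diclofenac": 1.2, "celecoxib": 1.05},
    },
)


@dataclass
class HpeModelSpec:
    """One indication's configured HPE/comparator model pair."""

    indication: str
    hpe_arm: TransitionModel
    comparator_arm: TransitionModel
    cohort_profile: dict
    parameters: dict
    cycle_length: float = 1.0
    exposure_duration: float | None = None  # None = full horizon
    nsaid_mix: NsaidMix = field(default_factory=lambda: BASE_CASE_MIX)

    @property
    def structure(self) -> ModelStructure:
        return STRUCTURES[self.indication]


def _combined_annual_probability(
    base: float, excess: float, mix_factor: float
) -> float:
    """HPE-arm annual probability from comparator-level and excess parts.

    Hazards add (`rate = rate_base + rate_excess`); the weighted-mix factor
    scales the resulting HPE-arm event rate before conversion back to a
    probability, so the base case (factor 1, zero excess in the comparator)
    is an identity.
    """
    rate = probability_to_rate(min(base, 1 - 1e-12)) + probability_to_rate(
        min(excess, 1 - 1e-12)
    )
    return rate_to_probability(rate * mix_factor)


def _arm_matrix(
    structure: ModelStructure,
    values: Mapping[str, float],
    arm: str,
    cycle_length: float,
    mix: NsaidMix,
) -> np.ndarray:
    names = structure.state_names()
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    matrix = np.zeros((n, n))

    def value(param: str) -> float:
        try:
            return float(values[param])
        except KeyError:
            raise MissingParameterError(param, structure.indication) from None

    by_source: dict[str, list[TransitionDef]] = {}
    for t in structure.transitions:
        by_source.setdefault(t.source, []).append(t)

    for s in structure.states:
        i = idx[s.name]
        if s.absorbing:
            matrix[i, i] = 1.0
            continue
        row_specified = 0.0
        for t in by_source.get(s.name, ()):
            p_annual = value(t.param)
            if t.by_arm and arm == "hpe":
                factor = mix.rate_factor(t.event_class) if t.event_class else 1.0
                p_annual = _combined_annual_probability(
                    p_annual, value(t.param + "_excess"), factor
                )
            p_cycle = rescale_probability(p_annual, cycle_length)
            matrix[i, idx[t.target]] += p_cycle
            row_specified += p_cycle
        if row_specified > 1.0 + 1e-12:
            raise RowOverflowError(structure.indication, s.name, row_specified)
        residual_target = structure.default_target.get(s.name, s.name)
        matrix[i, idx[residual_target]] += 1.0 - row_specified
    return matrix


def _arm_states(
    structure: ModelStructure, values: Mapping[str, float]
) -> tuple[HealthState, ...]:
    states = []
    for s in structure.states:
        if s.absorbing:
            states.append(
                HealthState(s.name, utility=0.0, annual_cost=0.0, is_absorbing=True)
            )
            continue
        for param in (s.u_param(), s.c_param()):
            if param not in values:
                raise MissingParameterError(param, structure.indication)
        states.append(
            HealthState(
                s.name,
                utility=float(values[s.u_param()]),
                annual_cost=float(values[s.c_param()]),
                is_acute_event=s.acute,
            )
        )
    return tuple(states)


def build_model(
    indication: str,
    parameters: Mapping[str, ParameterSpec] | Mapping[str, float],
    cycle_length: float = 1.0,
    nsaid_mix: NsaidMix | None = None,
) -> HpeModelSpec:
    """Build and validate one indication's HPE/comparator model pair.

    ``parameters`` maps parameter names to :class:`ParameterSpec` objects
    (point values are used here; uncertainty descriptors feed the PSA) or
    to plain floats.  Raises :class:`MissingParameterError` naming the first
    absent parameter, or ``KeyError`` for an unknown indication.
    """
    if indication not in STRUCTURES:
        raise KeyError(
            f"unknown indication '{indication}'; expected one of {INDICATIONS}"
        )
    structure = STRUCTURES[indication]
    mix = nsaid_mix or BASE_CASE_MIX
    values = point_values(parameters)
    states = _arm_states(structure, values)
    arms = {}
    for arm in ("hpe", "comparator"):
        matrix = _arm_matrix(structure, values, arm, cycle_length, mix)
        arms[arm] = validate_transition_model(
            TransitionModel(states=states, matrix=matrix, cycle_length=cycle_length)
        )
    return HpeModelSpec(
        indication=indication,
        hpe_arm=arms["hpe"],
        comparator_arm=arms["comparator"],
        cohort_profile=dict(structure.cohort_profile),
        parameters=dict(parameters),
        cycle_length=cycle_length,
        nsaid_mix=mix,
    )


def apply_exposure_rule(spec: HpeModelSpec, rule: ExposureRule) -> HpeModelSpec:
    """Limit the duration for which HPE-arm probabilities apply.

    The duration must sit on the cycle grid.  Cessation after an adverse
    event is structural in the state graph, so ``cessation_on_event`` is
    accepted for completeness but cannot be switched off.
    """
    n = rule.duration_years / spec.cycle_length
    if abs(n - round(n)) > 1e-9 or n <= 0:
        raise ModelValidationError(
            f"exposure duration {rule.duration_years!r} y is not on the "
            f"{spec.cycle_length!r}-y cycle grid"
        )
    if not rule.cessation_on_event:
        raise ModelValidationError(
            "cessation on event is structural in these models and cannot be disabled"
        )
    return dataclasses.replace(spec, exposure_duration=rule.duration_years)


def apply_nsaid_mix(spec: HpeModelSpec, mix: NsaidMix) -> HpeModelSpec:
    """Rebuild the pair with HPE-arm event rates scaled by the weighted mix."""
    rebuilt = build_model(
        spec.indication, spec.parameters, spec.cycle_length, nsaid_mix=mix
    )
    return dataclasses.replace(
        rebuilt, exposure_duration=spec.exposure_duration
    )


@dataclass
class PairResult:
    """Both arms' per-person totals and their increment for one indication."""

    indication: str
    hpe: ArmResult
    comparator: ArmResult
    increment: IncrementalResult


def initial_occupancy(spec: HpeModelSpec) -> np.ndarray:
    """The whole cohort starts in the exposed 'well' state."""
    init = np.zeros(spec.hpe_arm.n_states)
    init[spec.hpe_arm.index("well")] = 1.0
    return init


def run_arm(spec: HpeModelSpec, arm: str, config: EngineConfig) -> ArmResult:
    """Run one arm's cohort trace and accumulate discounted totals."""
    if abs(spec.cycle_length - config.cycle_length_years) > 1e-12:
        raise ModelValidationError(
            "model cycle length does not match the engine configuration"
        )
    model = spec.hpe_arm if arm == "hpe" else spec.comparator_arm
    n_cycles = config.n_cycles
    if arm == "hpe" and spec.exposure_duration is not None:
        exposed = int(round(spec.exposure_duration / spec.cycle_length))
        exposed = min(exposed, n_cycles)
        segments = [(model, exposed), (spec.comparator_arm, n_cycles - exposed)]
        segments = [(m, k) for m, k in segments if k > 0]
    else:
        segments = [(model, n_cycles)]
    trace = run_cohort_piecewise(segments, initial_occupancy(spec))
    result = accumulate_arm(
        trace,
        model.states,
        DiscountSpec(annual_rate=config.discount_rate),
        half_cycle_correction=config.half_cycle_correction,
        accrue_cycle_zero=config.accrue_cycle_zero,
    )
    result.metadata["arm"] = arm
    result.metadata["indication"] = spec.indication
    result.metadata["exposure_duration_years"] = (
        spec.exposure_duration
        if spec.exposure_duration is not None
        else config.horizon_years
    )
    return result


def run_pair(spec: HpeModelSpec, config: EngineConfig) -> PairResult:
    """Run both arms under identical settings and form the increment."""
    hpe = run_arm(spec, "hpe", config)
    comparator = run_arm(spec, "comparator", config)
    return PairResult(
        indication=spec.indication,
        hpe=hpe,
        comparator=comparator,
        increment=incremental(hpe, comparator),
    )


def build_all_models(
    tables: Mapping[str, Mapping[str, ParameterSpec]],
    cycle_length: float = 1.0,
    nsaid_mix: NsaidMix | None = None,
) -> dict[str, HpeModelSpec]:
    """Build every indication's model pair from a full set of tables."""
    return {
        indication: build_model(indication, tables[indication], cycle_length, nsaid_mix)
        for indication in INDICATIONS
    }
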