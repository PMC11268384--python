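"""Sensitivity analyses as declarative scenario configurations.

Every sensitivity analysis is a :class:`ScenarioSpec` describing overrides
of the base pipeline: horizon (5/10/20 years), discount rate (0 or 3.5%),
exposure duration (0.25–10 years), minimising overlap of at-risk
populations, and the weighted-average NSAID mix.  Scenarios re-run the
full pipeline with the same seed as the base case, so differences are
attributable solely to the overrides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden import (
    BurdenTable,
    NationalCount,
    PopulationSpec,
    PrevalenceRecord,
    national_burden,
    overlap_adjustment,
    scale_to_population,
)
from .config import EngineConfig
from .models import (
    ExposureRule,
    HpeModelSpec,
    NsaidMix,
    WEIGHTED_AVERAGE_MIX,
    apply_exposure_rule,
    build_all_models,
    run_pair,
)
from .parameters import ParameterSpec
from .psa import PsaDraws, PsaSummary, run_psa, summarise_psa


@dataclass(frozen=True)
class ScenarioSpec:
    """Overrides applied on top of the base run configuration."""

    name: str
    horizon_years: float | None = None  # 5, 10 or 20
    discount_rate: float | None = None  # 0 or 0.035
    exposure_duration_years: float | None = None  # within (0.25, 10]
    overlap_adjust: bool = False
    nsaid_mix: NsaidMix | None = None

    def __post_init__(self):
        if self.horizon_years is not None and self.horizon_years not in (5, 10, 20):
            raise ValueError("horizon override must be 5, 10 or 20 years")
        if self.discount_rate is not None and not 0 <= self.discount_rate <= 0.1:
            raise ValueError("discount override outside the supported range")
        if self.exposure_duration_years is not None and not (
            0.25 <= self.exposure_duration_years <= 10
        ):
            raise ValueError("exposure duration override outside [0.25, 10] years")


STANDARD_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("base"),
    ScenarioSpec("five_year", horizon_years=5),
    ScenarioSpec("twenty_year", horizon_years=20),
    ScenarioSpec("no_discount", discount_rate=0.0),
    ScenarioSpec("minimise_overlap", overlap_adjust=True),
    ScenarioSpec("weighted_nsaid_mix", nsaid_mix=WEIGHTED_AVERAGE_MIX),
)


@dataclass
class ScenarioResult:
    name: str
    config: EngineConfig
    counts: dict[str, NationalCount]
    burden: BurdenTable
    summaries: dict[str, PsaSummary]
    draws: PsaDraws


def _compatible_cycle_length(duration: float, config: EngineConfig) -> float:
    """Largest standard cycle length that fits both duration and horizon."""
    for cl in (config.cycle_length_years, 1.0, 0.5, 0.25):
        n_d = duration / cl
        n_h = config.horizon_years / cl
        if abs(n_d - round(n_d)) < 1e-9 and abs(n_h - round(n_h)) < 1e-9 and n_d >= 1:
            return cl
    raise ValueError(
        f"no supported cycle length fits exposure duration {duration!r} y"
    )


def run_scenario(
    tables: Mapping[str, Mapping[str, ParameterSpec]],
    prevalence: Mapping[str, PrevalenceRecord],
    population: PopulationSpec,
    scenario: ScenarioSpec,
    base_config: EngineConfig | None = None,
    psa_samples: int = 10_000,
    seed: int = 0,
) -> ScenarioResult:
    """Re-run the full pipeline under one scenario's overrides."""
    config = base_config or EngineConfig()
    changes: dict = {}
    if scenario.horizon_years is not None:
        changes["horizon_years"] = float(scenario.horizon_years)
    if scenario.discount_rate is not None:
        changes["discount_rate"] = float(scenario.discount_rate)
    if scenario.exposure_duration_years is not None:
        probe = config.replace(**changes)
        changes["cycle_length_years"] = _compatible_cycle_length(
            scenario.exposure_duration_years, probe
        )
    config = config.replace(**changes)

    records = dict(prevalence)
    if scenario.overlap_adjust:
        records = overlap_adjustment(records)
    counts = {
        k: scale_to_population(r, population) for k, r in records.items()
    }

    models = build_all_models(
        tables, config.cycle_length_years, nsaid_mix=scenario.nsaid_mix
    )
    if scenario.exposure_duration_years is not None:
        rule = ExposureRule(duration_years=scenario.exposure_duration_years)
        models = {k: apply_exposure_rule(m, rule) for k, m in models.items()}

    draws = run_psa(models, psa_samples, seed=seed, config=config)
    burden = national_burden(counts, draws)
    return ScenarioResult(
        name=scenario.name,
        config=config,
        counts=counts,
        burden=burden,
        summaries=summarise_psa(draws),
        draws=draws,
    )


@dataclass
class HarmAccrualCurve:
    """Harm and cost versus assumed exposure duration for one indication."""

    indication: str
    table: pd.DataFrame  # columns: duration_years, delta_qalys, delta_cost
    half_harm_duration_years: float

    @property
    def full_exposure_delta_qalys(self) -> float:
        return float(self.table["delta_qalys"].iloc[-1])


def harm_accrual_curve(
    spec: HpeModelSpec,
    durations: Sequence[float],
    config: EngineConfig,
) -> HarmAccrualCurve:
    """Deterministic QALY loss and cost by exposure duration.

    Durations must be sorted, positive, within the horizon and on the
    model's cycle grid.  The half-harm duration — the exposure length at
    which 50% of the full-exposure QALY loss is reached — is linearly
    interpolated on the curve.
    """
    durations = list(durations)
    if durations != sorted(durations) or durations[0] <= 0:
        raise ValueError("durations must be sorted and positive")
    if durations[-1] > config.horizon_years:
        raise ValueError("durations must lie within the horizon")
    rows = []
    for d in durations:
        limited = apply_exposure_rule(spec, ExposureRule(duration_years=d))
        pair = run_pair(limited, config)
        rows.append(
            {
                "duration_years": d,
                "delta_qalys": pair.increment.delta_qalys,
                "delta_cost": pair.increment.delta_cost,
            }
        )
    table = pd.DataFrame(rows)
    full = table["delta_qalys"].iloc[-1]
    harm = -table["delta_qalys"].to_numpy()  # positive loss, non-decreasing
    target = -0.5 * full
    half = float(
        np.interp(target, harm, table["duration_years"].to_numpy())
    )
    return HarmAccrualCurve(
        indication=spec.indication, table=table, half_harm_duration_years=half
    )
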