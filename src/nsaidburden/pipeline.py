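"""End-to-end pipeline and report emission.

Runs the deterministic base case, the PSA, the national scaling and the
configured scenarios, and writes the outputs as delimited text: a
per-patient results table, the national burden table with its scenario
block, an excess-events table, the cost-effectiveness-plane cloud, a
harm-accrual table, and a JSON metadata file recording the seed, settings
and package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .burden import (
    BurdenTable,
    PopulationSpec,
    PrevalenceRecord,
    excess_events,
    national_burden,
    rate_per_1000,
    read_prevalence,
    round_half_up,
    scale_to_population,
    share_of_total,
)
from .config import EngineConfig, RunConfig
from .datasets import england_population, england_prevalence
from .models import INDICATIONS, build_all_models, run_pair
from .parameters import ParameterSpec, read_parameter_tables
from .psa import ce_plane_summary, run_psa, summarise_psa
from .scenarios import (
    STANDARD_SCENARIOS,
    HarmAccrualCurve,
    ScenarioSpec,
    harm_accrual_curve,
    run_scenario,
)
from .synthetic import generate_parameter_tables

log = logging.getLogger("nsaidburden")

_DEFAULT_ACCRUAL_DURATIONS = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 7.5, 10.0)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


def _load_parameters(source: str, seed: int):
    if source.startswith("synthetic:"):
        preset = source.split(":", 1)[1]
        return generate_parameter_tables(seed, preset=preset).tables
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"parameter table not found: {path}")
    return read_parameter_tables(path)


def _load_prevalence(source: str) -> dict[str, PrevalenceRecord]:
    if source == "published":
        return england_prevalence()
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"prevalence file not found: {path}")
    return read_prevalence(path)


def _per_patient_frame(summaries) -> pd.DataFrame:
    rows = []
    for ind, s in summaries.items():
        rows.append(
            {
                "indication": ind,
                "cost_hpe": s.costs_hpe.mean,
                "cost_hpe_lower": s.costs_hpe.lower,
                "cost_hpe_upper": s.costs_hpe.upper,
                "cost_comparator": s.costs_comparator.mean,
                "cost_comparator_lower": s.costs_comparator.lower,
                "cost_comparator_upper": s.costs_comparator.upper,
                "delta_cost": s.delta_cost.mean,
                "delta_cost_lower": s.delta_cost.lower,
                "delta_cost_upper": s.delta_cost.upper,
                "qalys_hpe": s.qalys_hpe.mean,
                "qalys_hpe_lower": s.qalys_hpe.lower,
                "qalys_hpe_upper": s.qalys_hpe.upper,
                "qalys_comparator": s.qalys_comparator.mean,
                "qalys_comparator_lower": s.qalys_comparator.lower,
                "qalys_comparator_upper": s.qalys_comparator.upper,
                "delta_qalys": s.delta_qalys.mean,
                "delta_qalys_lower": s.delta_qalys.lower,
                "delta_qalys_upper": s.delta_qalys.upper,
            }
        )
    return pd.DataFrame(rows)


def _burden_block(name: str, table: BurdenTable) -> pd.DataFrame:
    frame = table.to_frame()
    frame.insert(0, "scenario", name)
    return frame


@dataclass
class ReportBundle:
    """Paths of every file the pipeline wrote."""

    output_dir: Path
    files: dict[str, Path]


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the configured analysis end to end and write all report tables."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    engine = config.engine

    def stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            log.error("stage %s failed: %s", name, exc)
            raise PipelineError(name, exc) from exc

    tables = stage("load_parameters", lambda: _load_parameters(config.parameters, config.seed))
    prevalence = stage("load_prevalence", lambda: _load_prevalence(config.prevalence))
    population = PopulationSpec(n_registered=config.n_registered)

    models = stage(
        "build_models", lambda: build_all_models(tables, engine.cycle_length_years)
    )
    pairs = stage(
        "deterministic_run", lambda: {k: run_pair(m, engine) for k, m in models.items()}
    )
    draws = stage(
        "psa", lambda: run_psa(models, config.psa_samples, config.seed, engine)
    )
    summaries = summarise_psa(draws)

    counts = {k: scale_to_population(r, population) for k, r in prevalence.items()}
    base_burden = stage("burden", lambda: national_burden(counts, draws))

    # Table-2-style per-patient results
    per_patient = _per_patient_frame(summaries)
    files["per_patient"] = out / "per_patient_results.csv"
    per_patient.to_csv(files["per_patient"], index=False)

    # Prevalence and national counts
    prev_rows = []
    for ind, rec in prevalence.items():
        affected = rate_per_1000(rec, "affected")
        at_risk = rate_per_1000(rec, "at_risk")
        nc = counts[ind]
        prev_rows.append(
            {
                "indication": ind,
                "n_at_risk": rec.n_at_risk,
                "at_risk_per_1000": round_half_up(at_risk.rate, 2),
                "n_affected": rec.n_affected,
                "affected_per_1000": round_half_up(affected.rate, 2),
                "affected_per_1000_lower": round_half_up(affected.lower, 2),
                "affected_per_1000_upper": round_half_up(affected.upper, 2),
                "national_affected": nc.count,
                "national_affected_lower": nc.lower,
                "national_affected_upper": nc.upper,
                "share_pct": round_half_up(share_of_total(counts)[ind], 1),
            }
        )
    files["prevalence"] = out / "prevalence.csv"
    pd.DataFrame(prev_rows).to_csv(files["prevalence"], index=False)

    # Burden table with scenario block
    blocks = [_burden_block("base", base_burden)]
    scenario_specs = [s for s in STANDARD_SCENARIOS if s.name != "base"]
    if config.scenarios:
        scenario_specs = [s for s in scenario_specs if s.name in config.scenarios]
    for sspec in scenario_specs:
        result = stage(
            f"scenario:{sspec.name}",
            lambda sspec=sspec: run_scenario(
                tables,
                prevalence,
                population,
                sspec,
                base_config=engine,
                psa_samples=config.psa_samples,
                seed=config.seed,
            ),
        )
        blocks.append(_burden_block(sspec.name, result.burden))
    files["burden"] = out / "burden_table.csv"
    pd.concat(blocks, ignore_index=True).to_csv(files["burden"], index=False)

    # Excess events (Fig-1 layout)
    excess_rows = []
    for ind, pair in pairs.items():
        ev = excess_events(pair.hpe, pair.comparator, counts[ind].count)
        for event, value in ev.items():
            excess_rows.append(
                {"indication": ind, "event": event, "excess_events": round_half_up(value)}
            )
    files["excess_events"] = out / "excess_events.csv"
    pd.DataFrame(excess_rows).to_csv(files["excess_events"], index=False)

    # CE-plane cloud of national totals (Fig-2 data)
    assert base_burden.qaly_samples is not None
    plane = ce_plane_summary(base_burden.qaly_samples, base_burden.cost_samples_millions)
    cloud = pd.DataFrame(
        {
            "delta_qalys_total": plane.delta_qalys,
            "delta_cost_total_m": plane.delta_cost,
        }
    )
    files["ce_plane"] = out / "ce_plane_cloud.csv"
    cloud.to_csv(files["ce_plane"], index=False)
    ellipse = pd.DataFrame(plane.ellipse_points(), columns=["delta_qalys_total", "delta_cost_total_m"])
    files["ce_ellipse"] = out / "ce_plane_ellipse.csv"
    ellipse.to_csv(files["ce_ellipse"], index=False)

    # Harm-accrual curves (Fig-3 data), quarterly grid
    accrual_engine = EngineConfig(
        horizon_years=engine.horizon_years,
        cycle_length_years=0.25,
        discount_rate=engine.discount_rate,
        half_cycle_correction=engine.half_cycle_correction,
        accrue_cycle_zero=engine.accrue_cycle_zero,
    )
    accrual_models = build_all_models(tables, 0.25)
    durations = [d for d in _DEFAULT_ACCRUAL_DURATIONS if d <= engine.horizon_years]
    accrual_frames = []
    for ind, spec in accrual_models.items():
        curve = stage(
            f"harm_accrual:{ind}",
            lambda spec=spec: harm_accrual_curve(spec, durations, accrual_engine),
        )
        t = curve.table.copy()
        t.insert(0, "indication", ind)
        t["half_harm_duration_years"] = curve.half_harm_duration_years
        accrual_frames.append(t)
    files["harm_accrual"] = out / "harm_accrual.csv"
    pd.concat(accrual_frames, ignore_index=True).to_csv(files["harm_accrual"], index=False)

    # Run metadata
    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "psa_samples": config.psa_samples,
        "psa_rejections": draws.rejections,
        "engine": {
            "horizon_years": engine.horizon_years,
            "cycle_length_years": engine.cycle_length_years,
            "discount_rate": engine.discount_rate,
            "half_cycle_correction": engine.half_cycle_correction,
            "accrue_cycle_zero": engine.accrue_cycle_zero,
        },
        "parameters": config.parameters,
        "prevalence": config.prevalence,
        "n_registered": config.n_registered,
        "prop_simulations_cost_increase": plane.prop_cost_increase,
        "prop_simulations_qaly_loss": plane.prop_qaly_loss,
    }
    files["metadata"] = out / "run_metadata.json"
    with open(files["metadata"], "w") as fh:
        json.dump(metadata, fh, indent=2)

    return ReportBundle(output_dir=out, files=files)
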