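"""National burden: prevalence rates, population scaling, totals.

Converts indicator-level prevalence records (patients affected / registered
patients in the audited sample) into per-1000 rates with binomial
confidence intervals, scales affected counts to the registered population
of England, and multiplies national counts by per-person QALY and cost
increments — per PSA sample, so the credibility intervals on national
totals reflect parameter uncertainty — to produce the national burden
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .markov import ArmResult, IncrementalResult
from .psa import PsaDraws, SummaryStat, credibility_interval


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style rounding (0.5 always rounds away from zero)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class PrevalenceRecord:
    """Counts for one indicator from the audited practice sample."""

    indication: str
    n_at_risk: int
    n_affected: int
    denominator: int

    def __post_init__(self):
        if not 0 <= self.n_affected <= self.n_at_risk <= self.denominator:
            raise ValueError(
                f"{self.indication}: need 0 <= affected <= at-risk <= denominator, "
                f"got {self.n_affected} / {self.n_at_risk} / {self.denominator}"
            )


@dataclass(frozen=True)
class PopulationSpec:
    """Registered population the sample prevalence is scaled up to."""

    n_registered: int = 63_049_603
    reference_date: str = "2023-12-01"

    def __post_init__(self):
        if self.n_registered <= 0:
            raise ValueError("n_registered must be positive")


@dataclass(frozen=True)
class RateResult:
    """Per-1000 rate with its 95% CI (full precision; round for display)."""

    rate: float
    lower: float
    upper: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return tuple(round_half_up(v, ndigits) for v in (self.rate, self.lower, self.upper))


def rate_per_1000(
    record: PrevalenceRecord,
    which: str = "affected",
    ci_method: str = "wald",
    level: float = 0.95,
) -> RateResult:
    """Events per 1000 registered patients with a binomial 95% CI.

    ``ci_method`` is ``wald`` (normal approximation, the reporting
    convention here) or ``wilson``.
    """
    if record.denominator <= 0:
        raise ValueError("denominator must be positive")
    count = {"affected": record.n_affected, "at_risk": record.n_at_risk}[which]
    lo, hi = proportion_confint(
        count,
        record.denominator,
        alpha=1 - level,
        method={"wald": "normal", "wilson": "wilson"}[ci_method],
    )
    return RateResult(
        rate=1000.0 * count / record.denominator,
        lower=1000.0 * float(lo),
        upper=1000.0 * float(hi),
    )


@dataclass(frozen=True)
class NationalCount:
    """Affected patients scaled to the registered population."""

    indication: str
    count: int
    lower: int
    upper: int


def scale_to_population(
    record: PrevalenceRecord, pop: PopulationSpec, ci_method: str = "wald"
) -> NationalCount:
    """Scale the sample prevalence up to the registered population.

    The point count and both CI endpoints are the sample proportions
    multiplied by ``n_registered`` and rounded half-up to whole patients.
    """
    rate = rate_per_1000(record, "affected", ci_method)
    scale = pop.n_registered / 1000.0
    return NationalCount(
        indication=record.indication,
        count=int(round_half_up(rate.rate * scale)),
        lower=int(round_half_up(rate.lower * scale)),
        upper=int(round_half_up(rate.upper * scale)),
    )


@dataclass
class BurdenRow:
    indication: str
    n_affected: int
    qaly_total: SummaryStat
    cost_total_millions: SummaryStat


@dataclass
class BurdenTable:
    """National totals per indication plus their sum.

    ``qaly_total`` carries the signed QALY change (negative = loss);
    ``cost_total_millions`` is in GBP millions.  When built from PSA draws
    the per-sample grand totals are retained so additivity can be checked
    exactly before any rounding.
    """

    rows: dict[str, BurdenRow]
    total_qalys: SummaryStat
    total_cost_millions: SummaryStat
    qaly_samples: np.ndarray | None = None
    cost_samples_millions: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows.values():
            records.append(
                {
                    "indication": row.indication,
                    "n_affected": row.n_affected,
                    "qaly_total": round_half_up(row.qaly_total.mean),
                    "qaly_lower": round_half_up(row.qaly_total.lower),
                    "qaly_upper": round_half_up(row.qaly_total.upper),
                    "cost_m": round_half_up(row.cost_total_millions.mean, 2),
                    "cost_m_lower": round_half_up(row.cost_total_millions.lower, 2),
                    "cost_m_upper": round_half_up(row.cost_total_millions.upper, 2),
                }
            )
        records.append(
            {
                "indication": "total",
                "n_affected": sum(r.n_affected for r in self.rows.values()),
                "qaly_total": round_half_up(self.total_qalys.mean),
                "qaly_lower": round_half_up(self.total_qalys.lower),
                "qaly_upper": round_half_up(self.total_qalys.upper),
                "cost_m": round_half_up(self.total_cost_millions.mean, 2),
                "cost_m_lower": round_half_up(self.total_cost_millions.lower, 2),
                "cost_m_upper": round_half_up(self.total_cost_millions.upper, 2),
            }
        )
        return pd.DataFrame(records)

    @classmethod
    def from_point_components(
        cls,
        qaly_components: Mapping[str, float],
        cost_m_components: Mapping[str, float],
        counts: Mapping[str, int] | None = None,
    ) -> "BurdenTable":
        """Build a deterministic table from per-indication point totals.

        Grand totals are computed as the sums of the supplied components.
        """
        rows = {}
        for ind in qaly_components:
            q = float(qaly_components[ind])
            c = float(cost_m_components[ind])
            rows[ind] = BurdenRow(
                indication=ind,
                n_affected=int(counts[ind]) if counts else 0,
                qaly_total=SummaryStat(q, q, q),
                cost_total_millions=SummaryStat(c, c, c),
            )
        tq = sum(qaly_components.values())
        tc = sum(cost_m_components.values())
        return cls(
            rows=rows,
            total_qalys=SummaryStat(tq, tq, tq),
            total_cost_millions=SummaryStat(tc, tc, tc),
        )


def _stat_from_samples(values: np.ndarray) -> SummaryStat:
    lo, hi = credibility_interval(values)
    mean = float(np.mean(values))
    return SummaryStat(mean, lo, hi, mean_outside_ci=not (lo <= mean <= hi))


def national_burden(
    counts: Mapping[str, NationalCount | int],
    draws: PsaDraws,
) -> BurdenTable:
    """National count x per-person increment, per PSA sample, summarised.

    Grand totals are formed per sample and then summarised, so they are the
    exact sum of the per-indication samples before any rounding.
    """
    qaly_samples = np.zeros(draws.n_samples)
    cost_samples = np.zeros(draws.n_samples)
    rows: dict[str, BurdenRow] = {}
    for indication, model_draws in draws.models.items():
        if indication not in counts:
            raise KeyError(f"no national count for indication '{indication}'")
        nc = counts[indication]
        n = nc.count if isinstance(nc, NationalCount) else int(nc)
        q = n * model_draws.delta_qalys
        c = n * model_draws.delta_cost / 1e6
        qaly_samples += q
        cost_samples += c
        rows[indication] = BurdenRow(
            indication=indication,
            n_affected=n,
            qaly_total=_stat_from_samples(q),
            cost_total_millions=_stat_from_samples(c),
        )
    missing = set(counts) - set(draws.models)
    if missing:
        raise KeyError(f"no increment draws for indications {sorted(missing)}")
    return BurdenTable(
        rows=rows,
        total_qalys=_stat_from_samples(qaly_samples),
        total_cost_millions=_stat_from_samples(cost_samples),
        qaly_samples=qaly_samples,
        cost_samples_millions=cost_samples,
    )


def share_of_total(counts: Mapping[str, NationalCount | int]) -> dict[str, float]:
    """Each indication's share of all events, as a percentage."""
    values = {
        k: (v.count if isinstance(v, NationalCount) else float(v))
        for k, v in counts.items()
    }
    total = sum(values.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    return {k: 100.0 * v / total for k, v in values.items()}


def excess_events(
    hpe: ArmResult, comparator: ArmResult, count: float
) -> dict[str, float]:
    """Expected excess events nationally per event type (including death).

    ``(HPE-arm cumulative incidence - comparator incidence) x national
    count`` for every tracked adverse-event state and death.
    """
    out = {}
    for event, inc_hpe in hpe.event_cumulative_incidence.items():
        inc_comp = comparator.event_cumulative_incidence.get(event, 0.0)
        out[event] = (inc_hpe - inc_comp) * count
    return out


def overlap_adjustment(
    records: Mapping[str, PrevalenceRecord],
    older: str = "older_no_gpa",
    deducted: tuple[str, ...] = (
        "oral_anticoagulant",
        "heart_failure",
        "chronic_kidney_disease",
    ),
) -> dict[str, PrevalenceRecord]:
    """Minimise double counting across at-risk populations.

    The anticoagulant, heart-failure and CKD at-risk counts are deducted
    from the older-adult gastrointestinal-risk pool; the older-adult
    affected count is reduced proportionally to its at-risk reduction.
    Other records are unchanged.
    """
    for key in (older, *deducted):
        if key not in records:
            raise KeyError(f"overlap adjustment needs record '{key}'")
    base = records[older]
    deduction = sum(records[k].n_at_risk for k in deducted)
    adjusted_at_risk = base.n_at_risk - deduction
    if adjusted_at_risk < 0:
        raise ValueError(
            "deducted at-risk groups exceed the older-adult at-risk pool"
        )
    factor = adjusted_at_risk / base.n_at_risk if base.n_at_risk else 0.0
    adjusted_affected = int(round_half_up(base.n_affected * factor))
    out = dict(records)
    out[older] = PrevalenceRecord(
        indication=base.indication,
        n_at_risk=adjusted_at_risk,
        n_affected=adjusted_affected,
        denominator=base.denominator,
    )
    return out


def read_prevalence(path) -> dict[str, PrevalenceRecord]:
    frame = pd.read_csv(path)
    records = {}
    for row in frame.itertuples(index=False):
        records[row.indication] = PrevalenceRecord(
            indication=row.indication,
            n_at_risk=int(row.n_at_risk),
            n_affected=int(row.n_affected),
            denominator=int(row.denominator),
        )
    return records


def write_prevalence(records: Mapping[str, PrevalenceRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "indication": r.indication,
                "n_at_risk": r.n_at_risk,
                "n_affected": r.n_affected,
                "denominator": r.denominator,
            }
            for r in records.values()
        ]
    ).to_csv(path, index=False)
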