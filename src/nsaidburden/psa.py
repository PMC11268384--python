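"""Probabilistic sensitivity analysis.

Each input parameter gets a sampling distribution — beta for probabilities
and utilities, gamma for costs — moment-matched to its point value and
standard deviation.  The standard deviation comes from a reported standard
error, from 95% CI bounds as ``(upper - lower) / (2 x 1.96)``, or, when no
measure of uncertainty is available, is assumed to be 20% of the mean.
Each PSA sample draws every parameter once, applies the same draw to both
arms of every model (shared baselines are identical across arms within a
sample), recomputes both cohort traces, and records discounted QALYs and
costs per arm together with the increment.  All sampling is driven by a
single seeded generator, so results are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .config import EngineConfig
from .markov import IncrementalResult
from .models import HpeModelSpec, RowOverflowError, _arm_matrix, run_pair
from .parameters import ParameterError, ParameterSpec
import dataclasses


class SamplingError(ParameterError):
    """A distribution cannot be moment-matched to the requested parameter."""


@dataclass(frozen=True)
class FixedDistribution:
    value: float

    mean = property(lambda self: self.value)
    sd = property(lambda self: 0.0)

    def sample(self, rng: np.random.Generator, size=None):
        return np.full(size, self.value) if size is not None else self.value


@dataclass(frozen=True)
class BetaDistribution:
    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))

    def sample(self, rng: np.random.Generator, size=None):
        return rng.beta(self.alpha, self.beta, size=size)


@dataclass(frozen=True)
class GammaDistribution:
    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.shape) * self.scale)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, self.scale, size=size)


Distribution = FixedDistribution | BetaDistribution | GammaDistribution


def _target_sd(param: ParameterSpec) -> float:
    if param.uncertainty_kind == "se":
        return float(param.uncertainty)  # type: ignore[arg-type]
    if param.uncertainty_kind == "ci95":
        lo, hi = param.uncertainty  # type: ignore[misc]
        return (hi - lo) / (2 * 1.959963984540054)
    return 0.2 * param.point


def assign_distribution(param: ParameterSpec) -> Distribution:
    """Moment-match a sampling distribution to one parameter.

    Boundary point values (probability or utility at exactly 0 or 1, cost
    or sd of 0) degenerate to a fixed value, since beta moment-matching is
    undefined there.  Infeasible beta matching (``sd^2 >= m(1-m)``) raises
    :class:`SamplingError` naming the parameter.
    """
    if param.family == "fixed":
        return FixedDistribution(param.point)
    sd = _target_sd(param)
    m = param.point
    if sd == 0.0 or m == 0.0:
        return FixedDistribution(m)
    if param.family == "beta":
        if m >= 1.0:
            return FixedDistribution(m)
        if sd * sd >= m * (1.0 - m):
            raise SamplingError(
                f"{param.name}: beta moment-matching infeasible "
                f"(sd {sd:.4g} too large for mean {m:.4g})"
            )
        nu = m * (1.0 - m) / (sd * sd) - 1.0
        return BetaDistribution(alpha=m * nu, beta=(1.0 - m) * nu)
    if param.family == "gamma":
        return GammaDistribution(shape=(m / sd) ** 2, scale=sd * sd / m)
    raise SamplingError(f"{param.name}: unknown family '{param.family}'")


@dataclass
class ModelDraws:
    """Per-sample discounted totals for one indication."""

    qalys_hpe: np.ndarray
    qalys_comparator: np.ndarray
    costs_hpe: np.ndarray
    costs_comparator: np.ndarray

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.qalys_hpe - self.qalys_comparator

    @property
    def delta_cost(self) -> np.ndarray:
        return self.costs_hpe - self.costs_comparator


@dataclass
class PsaDraws:
    """All per-sample outputs of one PSA run."""

    n_samples: int
    seed: int
    models: dict[str, ModelDraws]
    rejections: dict[str, int] = field(default_factory=dict)

    def pooled_delta(self) -> tuple[np.ndarray, np.ndarray]:
        """Sum of per-indication increments per sample (equal weighting)."""
        dq = sum(m.delta_qalys for m in self.models.values())
        dc = sum(m.delta_cost for m in self.models.values())
        return np.asarray(dq), np.asarray(dc)


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    lower: float
    upper: float
    mean_outside_ci: bool = False


@dataclass
class PsaSummary:
    """Mean and 95% credibility interval per arm and for the increments."""

    indication: str
    qalys_hpe: SummaryStat
    qalys_comparator: SummaryStat
    costs_hpe: SummaryStat
    costs_comparator: SummaryStat
    delta_qalys: SummaryStat
    delta_cost: SummaryStat


def credibility_interval(draws: Sequence[float] | np.ndarray, level: float = 0.95):
    """Empirical central interval (linear-interpolation percentiles)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 samples for a credibility interval")
    tail = 100 * (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [tail, 100 - tail], method="linear")
    return float(lo), float(hi)


def _stat(values: np.ndarray, level: float = 0.95) -> SummaryStat:
    lo, hi = credibility_interval(values, level)
    mean = float(np.mean(values))
    return SummaryStat(mean, lo, hi, mean_outside_ci=not (lo <= mean <= hi))


def _sample_values(
    dists: Mapping[str, Distribution], rng: np.random.Generator
) -> dict[str, float]:
    return {name: float(d.sample(rng)) for name, d in dists.items()}


_MAX_RESAMPLE = 1000


def run_psa(
    models: Mapping[str, HpeModelSpec],
    n_samples: int,
    seed: int,
    config: EngineConfig | None = None,
) -> PsaDraws:
    """Propagate parameter uncertainty through every model pair.

    Any sampled parameter vector producing an invalid transition row
    (probabilities out of a state summing above 1) is rejected and the
    whole vector redrawn; rejection counts are reported per indication.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    config = config or EngineConfig()
    rng = np.random.default_rng(seed)
    out: dict[str, ModelDraws] = {}
    rejections: dict[str, int] = {}

    for indication, spec in models.items():
        dists = {
            name: assign_distribution(p) if isinstance(p, ParameterSpec) else FixedDistribution(float(p))
            for name, p in spec.parameters.items()
        }
        qh = np.empty(n_samples)
        qc = np.empty(n_samples)
        ch = np.empty(n_samples)
        cc = np.empty(n_samples)
        rejected = 0
        structure = spec.structure
        for i in range(n_samples):
            for _attempt in range(_MAX_RESAMPLE):
                values = _sample_values(dists, rng)
                try:
                    hpe_m = _arm_matrix(
                        structure, values, "hpe", spec.cycle_length, spec.nsaid_mix
                    )
                    comp_m = _arm_matrix(
                        structure, values, "comparator", spec.cycle_length, spec.nsaid_mix
                    )
                except RowOverflowError:
                    rejected += 1
                    continue
                break
            else:
                raise SamplingError(
                    f"{indication}: could not draw a valid parameter vector "
                    f"after {_MAX_RESAMPLE} attempts"
                )
            sampled = dataclasses.replace(
                spec,
                hpe_arm=dataclasses.replace(spec.hpe_arm, matrix=hpe_m,
                                            states=_states_with(spec, values)),
                comparator_arm=dataclasses.replace(spec.comparator_arm, matrix=comp_m,
                                                   states=_states_with(spec, values)),
                parameters=values,
            )
            pair = run_pair(sampled, config)
            qh[i] = pair.hpe.total_discounted_qalys
            qc[i] = pair.comparator.total_discounted_qalys
            ch[i] = pair.hpe.total_discounted_cost
            cc[i] = pair.comparator.total_discounted_cost
        out[indication] = ModelDraws(qh, qc, ch, cc)
        rejections[indication] = rejected

    return PsaDraws(n_samples=n_samples, seed=seed, models=out, rejections=rejections)


def _states_with(spec: HpeModelSpec, values: Mapping[str, float]):
    from .models import _arm_states

    return _arm_states(spec.structure, values)


def summarise_psa(draws: PsaDraws, level: float = 0.95) -> dict[str, PsaSummary]:
    """Per-indication means and credibility intervals (Table-2 layout)."""
    summaries = {}
    for indication, m in draws.models.items():
        summaries[indication] = PsaSummary(
            indication=indication,
            qalys_hpe=_stat(m.qalys_hpe, level),
            qalys_comparator=_stat(m.qalys_comparator, level),
            costs_hpe=_stat(m.costs_hpe, level),
            costs_comparator=_stat(m.costs_comparator, level),
            delta_qalys=_stat(m.delta_qalys, level),
            delta_cost=_stat(m.delta_cost, level),
        )
    return summaries


@dataclass
class CePlaneSummary:
    """Cost-effectiveness-plane cloud summary for incremental draws.

    ``prop_cost_increase`` is the share of samples with positive incremental
    cost; ``prop_qaly_loss`` the share with negative incremental QALYs.  The
    95% ellipse is the bivariate-normal contour at the chi-square(2) 0.95
    quantile fitted to the sample mean and covariance.
    """

    prop_cost_increase: float
    prop_qaly_loss: float
    mean: np.ndarray
    covariance: np.ndarray
    chi2_radius_sq: float
    degenerate: bool
    delta_qalys: np.ndarray
    delta_cost: np.ndarray

    def ellipse_points(self, n: int = 200) -> np.ndarray:
        """Boundary coordinates (n x 2: QALY, cost) for plotting."""
        if self.degenerate:
            return np.tile(self.mean, (n, 1))
        theta = np.linspace(0, 2 * np.pi, n)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        chol = np.linalg.cholesky(self.covariance)
        pts = (np.sqrt(self.chi2_radius_sq) * (chol @ circle)).T + self.mean
        return pts

    def fraction_within(self) -> float:
        """Share of the cloud inside the fitted 95% ellipse."""
        if self.degenerate:
            return 1.0
        pts = np.stack([self.delta_qalys, self.delta_cost], axis=1) - self.mean
        inv = np.linalg.inv(self.covariance)
        d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return float(np.mean(d2 <= self.chi2_radius_sq))


def ce_plane_summary(
    delta_qalys: Sequence[float] | np.ndarray,
    delta_cost: Sequence[float] | np.ndarray,
    level: float = 0.95,
) -> CePlaneSummary:
    """Summarise an incremental-draw cloud on the cost-effectiveness plane."""
    dq = np.asarray(delta_qalys, dtype=float)
    dc = np.asarray(delta_cost, dtype=float)
    if dq.size == 0 or dq.shape != dc.shape:
        raise ValueError("delta draws must be non-empty and aligned")
    mean = np.array([dq.mean(), dc.mean()])
    if dq.size < 2:
        cov = np.zeros((2, 2))
    else:
        cov = np.cov(np.stack([dq, dc]))
    degenerate = dq.size < 3 or np.linalg.matrix_rank(cov) < 2
    return CePlaneSummary(
        prop_cost_increase=float(np.mean(dc > 0)),
        prop_qaly_loss=float(np.mean(dq < 0)),
        mean=mean,
        covariance=cov,
        chi2_radius_sq=float(stats.chi2.ppf(level, df=2)),
        degenerate=degenerate,
        delta_qalys=dq,
        delta_cost=dc,
    )
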