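"""Cohort state-transition (Markov) engine.

A cohort model tracks the proportion of a closed cohort occupying each
health state at discrete cycles; a row-stochastic transition matrix
propagates the occupancy vector one cycle at a time.  Health-state rewards
(utility on the 0–1 dead–perfect-health scale, annual cost in GBP) accrue
per cycle occupied and are discounted back to model entry at a fixed annual
rate.  The engine is generic: the five NSAID indication models in
:mod:`nsaidburden.models` are built on top of it.

Conventions (all echoed in result metadata):

* ``discount_factor = (1 + r)^(-t)`` with ``t = cycle_index * cycle_length``
  years.
* By default, occupancy at cycles ``1..N`` accrues utility and cost; the
  entry distribution at cycle 0 accrues none.  This makes the undiscounted
  total for a single always-occupied state equal ``horizon x utility``
  exactly.  Both the cycle-0 accrual and a half-cycle correction (average
  of adjacent cycle occupancies) are available behind flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Tolerance on row-stochasticity and occupancy conservation.
ROW_SUM_TOL = 1e-9


class ModelValidationError(ValueError):
    """A transition structure violates a Markov-model invariant."""


@dataclass(frozen=True)
class HealthState:
    """A model health state with its per-year rewards.

    ``utility`` is on the [0, 1] scale (1 = perfect health, 0 = dead);
    ``annual_cost`` is GBP per year occupied.  ``is_absorbing`` marks death;
    ``is_acute_event`` marks states whose entry represents an adverse event
    (and, in the indication models, triggers cessation of the hazardous
    prescribing).
    """

    name: str
    utility: float
    annual_cost: float
    is_absorbing: bool = False
    is_acute_event: bool = False

    def __post_init__(self):
        if not 0.0 <= self.utility <= 1.0:
            raise ModelValidationError(
                f"state '{self.name}': utility {self.utility!r} outside [0, 1]"
            )
        if self.annual_cost < 0:
            raise ModelValidationError(
                f"state '{self.name}': negative annual cost {self.annual_cost!r}"
            )
        if self.is_absorbing and (self.utility != 0.0 or self.annual_cost != 0.0):
            raise ModelValidationError(
                f"absorbing state '{self.name}' must have zero utility and cost"
            )


@dataclass
class TransitionModel:
    """States plus a per-cycle transition matrix indexed ``[from, to]``."""

    states: tuple[HealthState, ...]
    matrix: np.ndarray
    cycle_length: float = 1.0

    def __post_init__(self):
        self.states = tuple(self.states)
        self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    @property
    def utilities(self) -> np.ndarray:
        return np.array([s.utility for s in self.states])

    @property
    def annual_costs(self) -> np.ndarray:
        return np.array([s.annual_cost for s in self.states])


def validate_transition_model(model: TransitionModel) -> TransitionModel:
    """Check row-stochasticity and absorbing-state structure.

    Returns the model unchanged when valid; raises
    :class:`ModelValidationError` naming the offending row otherwise.
    Renormalisation is deliberately refused — a bad row usually means a
    mistake in the parameter file and should surface, not be papered over.
    """
    n = model.n_states
    if model.matrix.shape != (n, n):
        raise ModelValidationError(
            f"matrix shape {model.matrix.shape} does not match {n} states"
        )
    if model.cycle_length <= 0:
        raise ModelValidationError("cycle_length must be positive")
    for i, state in enumerate(model.states):
        row = model.matrix[i]
        if np.any(row < -ROW_SUM_TOL) or np.any(row > 1 + ROW_SUM_TOL):
            raise ModelValidationError(
                f"row {i} ('{state.name}'): entries outside [0, 1]"
            )
        s = row.sum()
        if abs(s - 1.0) > ROW_SUM_TOL:
            raise ModelValidationError(
                f"row {i} ('{state.name}'): probabilities sum to {s!r}, not 1"
            )
        if state.is_absorbing:
            off_diagonal = s - row[i]
            if abs(off_diagonal) > ROW_SUM_TOL or abs(row[i] - 1.0) > ROW_SUM_TOL:
                raise ModelValidationError(
                    f"row {i} ('{state.name}'): absorbing state has "
                    f"off-diagonal transition mass"
                )
    return model


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate applied to future QALYs and costs (base 3.5%)."""

    annual_rate: float = 0.035
    enabled: bool = True

    def __post_init__(self):
        if self.annual_rate < 0:
            raise ModelValidationError("discount rate must be >= 0")


def discount_factor(spec: DiscountSpec, cycle_index: int, cycle_length: float) -> float:
    """``(1 + r)^(-t)`` at ``t = cycle_index * cycle_length`` years."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if not spec.enabled or spec.annual_rate == 0.0 or cycle_index == 0:
        return 1.0
    return float((1.0 + spec.annual_rate) ** (-(cycle_index * cycle_length)))


def _discount_factors(spec: DiscountSpec, n_cycles: int, cycle_length: float) -> np.ndarray:
    k = np.arange(n_cycles + 1)
    if not spec.enabled or spec.annual_rate == 0.0:
        return np.ones(n_cycles + 1)
    return (1.0 + spec.annual_rate) ** (-(k * cycle_length))


@dataclass
class CohortTrace:
    """State occupancy over cycles for one arm.

    ``occupancy[k, s]`` is the cohort proportion in state ``s`` at cycle
    ``k`` (cycle 0 = model entry).  ``entries[k, s]`` is the expected
    proportion newly entering state ``s`` during cycle ``k`` (zero at cycle
    0); summed over cycles it gives the expected number of entries per
    person, the quantity behind cumulative event incidence.
    """

    occupancy: np.ndarray
    entries: np.ndarray
    state_names: tuple[str, ...]
    cycle_length: float = 1.0

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def cumulative_entries(self) -> dict[str, float]:
        totals = self.entries[1:].sum(axis=0)
        return dict(zip(self.state_names, totals.tolist()))


def _propagate(
    segments: Sequence[tuple[TransitionModel, int]],
    initial_occupancy: np.ndarray,
) -> CohortTrace:
    first = segments[0][0]
    n = first.n_states
    total_cycles = sum(k for _, k in segments)
    occupancy = np.zeros((total_cycles + 1, n))
    entries = np.zeros((total_cycles + 1, n))
    occupancy[0] = initial_occupancy
    k = 0
    for model, n_cycles in segments:
        if model.state_names != first.state_names:
            raise ModelValidationError("piecewise segments must share the state set")
        m = model.matrix
        for _ in range(n_cycles):
            nxt = occupancy[k] @ m
            entries[k + 1] = nxt - occupancy[k] * np.diag(m)
            occupancy[k + 1] = nxt
            k += 1
    return CohortTrace(
        occupancy=occupancy,
        entries=entries,
        state_names=first.state_names,
        cycle_length=first.cycle_length,
    )


def run_cohort(
    model: TransitionModel,
    initial_occupancy: Sequence[float] | np.ndarray,
    horizon_years: float,
) -> CohortTrace:
    """Propagate a cohort for ``horizon_years`` and return its trace.

    The horizon must be a positive multiple of the cycle length; the trace
    has ``horizon / cycle_length + 1`` rows including the entry distribution.
    """
    init = np.asarray(initial_occupancy, dtype=float)
    if init.shape != (model.n_states,):
        raise ModelValidationError("initial occupancy length must match state count")
    if abs(init.sum() - 1.0) > ROW_SUM_TOL:
        raise ModelValidationError("initial occupancy must sum to 1")
    n_cycles = _cycles_on_grid(horizon_years, model.cycle_length)
    return _propagate([(model, n_cycles)], init)


def run_cohort_piecewise(
    segments: Sequence[tuple[TransitionModel, int]],
    initial_occupancy: Sequence[float] | np.ndarray,
) -> CohortTrace:
    """Propagate through a sequence of ``(model, n_cycles)`` segments.

    Used for the exposure-duration rule, where hazardous-prescribing
    transition probabilities apply for a limited number of cycles and
    comparator probabilities thereafter.
    """
    init = np.asarray(initial_occupancy, dtype=float)
    if abs(init.sum() - 1.0) > ROW_SUM_TOL:
        raise ModelValidationError("initial occupancy must sum to 1")
    return _propagate(list(segments), init)


def _cycles_on_grid(duration_years: float, cycle_length: float) -> int:
    n = duration_years / cycle_length
    if n <= 0 or abs(n - round(n)) > 1e-9:
        raise ModelValidationError(
            f"duration {duration_years!r} y is not a positive multiple of the "
            f"cycle length {cycle_length!r} y"
        )
    return int(round(n))


@dataclass
class ArmResult:
    """Discounted per-person totals for one arm over the model horizon."""

    total_discounted_qalys: float
    total_discounted_cost: float
    event_cumulative_incidence: dict[str, float]
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class IncrementalResult:
    """HPE arm minus comparator arm; negative ``delta_qalys`` is harm."""

    delta_qalys: float
    delta_cost: float


def accumulate_arm(
    trace: CohortTrace,
    states: Sequence[HealthState],
    discount: DiscountSpec,
    half_cycle_correction: bool = False,
    accrue_cycle_zero: bool = False,
) -> ArmResult:
    """Accumulate discounted QALYs and costs over a cohort trace.

    Per cycle the cohort accrues ``occupancy . utility x cycle_length``
    QALYs and the analogous cost, discounted by the factor at that cycle's
    time.  With ``half_cycle_correction`` the average of the occupancies at
    the start and end of each cycle accrues instead (discounted at the
    end-of-cycle time).  ``accrue_cycle_zero`` additionally accrues the
    entry distribution for one cycle at factor 1 (only meaningful without
    the half-cycle correction).
    """
    names = tuple(s.name for s in states)
    if names != trace.state_names:
        raise ModelValidationError("trace and state list are inconsistent")
    cl = trace.cycle_length
    u = np.array([s.utility for s in states])
    c = np.array([s.annual_cost for s in states])
    occ = trace.occupancy
    n_cycles = trace.n_cycles
    df = _discount_factors(discount, n_cycles, cl)

    if half_cycle_correction:
        weights = 0.5 * (occ[:-1] + occ[1:])  # rows k=1..N
    else:
        weights = occ[1:]
    qalys = float(np.sum(df[1:] * (weights @ u)) * cl)
    cost = float(np.sum(df[1:] * (weights @ c)) * cl)
    if accrue_cycle_zero and not half_cycle_correction:
        qalys += float(occ[0] @ u) * cl
        cost += float(occ[0] @ c) * cl

    incidence = {
        s.name: v
        for s, v in zip(states, trace.entries[1:].sum(axis=0))
        if s.is_acute_event or s.is_absorbing
    }
    return ArmResult(
        total_discounted_qalys=qalys,
        total_discounted_cost=cost,
        event_cumulative_incidence=incidence,
        metadata={
            "discount_rate": discount.annual_rate if discount.enabled else 0.0,
            "half_cycle_correction": half_cycle_correction,
            "accrue_cycle_zero": accrue_cycle_zero,
            "cycle_length_years": cl,
            "n_cycles": n_cycles,
        },
    )


def incremental(hpe: ArmResult, comparator: ArmResult) -> IncrementalResult:
    """Event-minus-no-event differences (negative QALY delta = harm)."""
    return IncrementalResult(
        delta_qalys=hpe.total_discounted_qalys - comparator.total_discounted_qalys,
        delta_cost=hpe.total_discounted_cost - comparator.total_discounted_cost,
    )


def rate_to_probability(annual_rate: float, cycle_length: float = 1.0) -> float:
    """Constant-hazard conversion ``p = 1 - exp(-rate x cycle_length)``."""
    if annual_rate < 0:
        raise ValueError("rate must be >= 0")
    return float(-np.expm1(-annual_rate * cycle_length))


def probability_to_rate(probability: float, cycle_length: float = 1.0) -> float:
    """Inverse of :func:`rate_to_probability`."""
    if not 0.0 <= probability < 1.0:
        raise ValueError("probability must be in [0, 1)")
    return float(-np.log1p(-probability) / cycle_length)


def rescale_probability(annual_probability: float, cycle_length: float) -> float:
    """Annual probability to per-cycle probability under a constant hazard."""
    return float(-np.expm1(cycle_length * np.log1p(-annual_probability)))
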