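"""Run configuration: engine settings, PSA settings, scenario switches."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class EngineConfig:
    """Cycle grid, horizon, discounting and cycle-accounting conventions.

    Defaults are the base case: a 10-year horizon of annual cycles with
    QALYs and costs discounted at 3.5% per annum, no half-cycle correction,
    and accrual from cycle 1 (the entry distribution accrues nothing).
    """

    horizon_years: float = 10.0
    cycle_length_years: float = 1.0
    discount_rate: float = 0.035
    half_cycle_correction: bool = False
    accrue_cycle_zero: bool = False

    def __post_init__(self):
        if self.horizon_years <= 0 or self.cycle_length_years <= 0:
            raise ValueError("horizon and cycle length must be positive")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        n = self.horizon_years / self.cycle_length_years
        if abs(n - round(n)) > 1e-9:
            raise ValueError("horizon must be a multiple of the cycle length")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_length_years))

    def replace(self, **changes) -> "EngineConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class RunConfig:
    """Full pipeline configuration, loadable from YAML.

    ``parameters`` is either a path to a parameter-table CSV or the literal
    ``synthetic:<preset>`` to generate tables at run time; ``prevalence`` is
    a path to a prevalence CSV or ``published`` for the England indicator
    counts shipped with the package.
    """

    parameters: str = "synthetic:paper_magnitude"
    prevalence: str = "published"
    n_registered: int = 63_049_603
    engine: EngineConfig = field(default_factory=EngineConfig)
    psa_samples: int = 10_000
    seed: int = 0
    scenarios: list[str] = field(default_factory=list)
    output_dir: str = "outputs"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        engine = EngineConfig(**raw.pop("engine", {}))
        return cls(engine=engine, **raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"run configuration not found: {path}")
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
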