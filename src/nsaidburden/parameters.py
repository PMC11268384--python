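"""Model input parameters and their tabular on-disk representation.

Every model input — a per-cycle transition probability, a health-state
utility, or an annual health-state cost — is a :class:`ParameterSpec`
carrying a point value, an uncertainty descriptor, and the distribution
family used when the parameter is sampled in probabilistic sensitivity
analysis.  Collections of parameters for the five indication models travel
as plain ``{model: {name: ParameterSpec}}`` mappings and round-trip through
a single CSV file with one row per parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

KINDS = ("probability", "utility", "cost")
UNCERTAINTY_KINDS = ("se", "ci95", "none")
FAMILIES = ("beta", "gamma", "fixed")

#: CSV column order for parameter tables.
TABLE_COLUMNS = (
    "model",
    "kind",
    "name",
    "value",
    "uncertainty_kind",
    "uncertainty",
    "family",
)


class ParameterError(ValueError):
    """A parameter value or descriptor is outside its support."""


class MissingParameterError(KeyError):
    """A model requires a parameter that the supplied table does not define."""

    def __init__(self, name: str, model: str | None = None):
        self.parameter = name
        self.model = model
        where = f" for model '{model}'" if model else ""
        super().__init__(f"missing parameter '{name}'{where}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


@dataclass(frozen=True)
class ParameterSpec:
    """One model input with its uncertainty description.

    Parameters
    ----------
    name
        Identifier, e.g. ``p_serious_gi`` or ``u_well``.
    kind
        ``probability`` | ``utility`` | ``cost``.
    point
        Point value: probabilities and utilities on [0, 1], costs in GBP
        per year (>= 0).
    uncertainty_kind
        ``se`` (standard error given), ``ci95`` (95% CI bounds given), or
        ``none`` (no measure available; the sampling layer then assumes the
        standard deviation is 20% of the mean).
    uncertainty
        A float for ``se``, a ``(lower, upper)`` pair for ``ci95``, ``None``
        otherwise.
    family
        ``beta`` for probabilities/utilities, ``gamma`` for costs,
        ``fixed`` for parameters excluded from sampling.
    """

    name: str
    kind: str
    point: float
    uncertainty_kind: str = "none"
    uncertainty: float | tuple[float, float] | None = None
    family: str = "fixed"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ParameterError(f"{self.name}: unknown kind '{self.kind}'")
        if self.uncertainty_kind not in UNCERTAINTY_KINDS:
            raise ParameterError(
                f"{self.name}: unknown uncertainty kind '{self.uncertainty_kind}'"
            )
        if self.family not in FAMILIES:
            raise ParameterError(f"{self.name}: unknown family '{self.family}'")
        if self.kind in ("probability", "utility") and not 0.0 <= self.point <= 1.0:
            raise ParameterError(
                f"{self.name}: {self.kind} {self.point!r} outside [0, 1]"
            )
        if self.kind == "cost" and self.point < 0:
            raise ParameterError(f"{self.name}: negative cost {self.point!r}")
        if self.uncertainty_kind == "se":
            if not isinstance(self.uncertainty, (int, float)) or self.uncertainty < 0:
                raise ParameterError(f"{self.name}: se must be a non-negative number")
        if self.uncertainty_kind == "ci95":
            try:
                lo, hi = self.uncertainty  # type: ignore[misc]
            except (TypeError, ValueError):
                raise ParameterError(f"{self.name}: ci95 needs (lower, upper)") from None
            if lo > hi:
                raise ParameterError(f"{self.name}: ci95 bounds reversed")


ParameterTable = Mapping[str, ParameterSpec]
ParameterTables = Mapping[str, ParameterTable]


def point_values(table: ParameterTable | Mapping[str, float]) -> dict[str, float]:
    """Collapse a parameter table to plain ``{name: point value}`` floats."""
    out: dict[str, float] = {}
    for name, spec in table.items():
        out[name] = spec.point if isinstance(spec, ParameterSpec) else float(spec)
    return out


def _encode_uncertainty(spec: ParameterSpec) -> str:
    if spec.uncertainty_kind == "se":
        return repr(float(spec.uncertainty))  # type: ignore[arg-type]
    if spec.uncertainty_kind == "ci95":
        lo, hi = spec.uncertainty  # type: ignore[misc]
        return f"{lo!r};{hi!r}"
    return ""


def _decode_uncertainty(kind: str, raw) -> float | tuple[float, float] | None:
    if kind == "se":
        return float(raw)
    if kind == "ci95":
        lo, hi = str(raw).split(";")
        return (float(lo), float(hi))
    return None


def tables_to_frame(tables: ParameterTables) -> pd.DataFrame:
    """Flatten per-model parameter tables into one tidy DataFrame."""
    rows = []
    for model, table in tables.items():
        for spec in table.values():
            rows.append(
                {
                    "model": model,
                    "kind": spec.kind,
                    "name": spec.name,
                    "value": spec.point,
                    "uncertainty_kind": spec.uncertainty_kind,
                    "uncertainty": _encode_uncertainty(spec),
                    "family": spec.family,
                }
            )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def frame_to_tables(frame: pd.DataFrame) -> dict[str, dict[str, ParameterSpec]]:
    tables: dict[str, dict[str, ParameterSpec]] = {}
    for row in frame.itertuples(index=False):
        spec = ParameterSpec(
            name=row.name,
            kind=row.kind,
            point=float(row.value),
            uncertainty_kind=row.uncertainty_kind,
            uncertainty=_decode_uncertainty(row.uncertainty_kind, row.uncertainty),
            family=row.family,
        )
        tables.setdefault(row.model, {})[spec.name] = spec
    return tables


def write_parameter_tables(tables: ParameterTables, path) -> None:
    tables_to_frame(tables).to_csv(path, index=False)


def read_parameter_tables(path) -> dict[str, dict[str, ParameterSpec]]:
    frame = pd.read_csv(path, keep_default_na=False)
    return frame_to_tables(frame)
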