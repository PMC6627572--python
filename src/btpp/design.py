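"""Experiment layout: temperature gradient, conditions, replicates, sample labels.

A thermal-shift experiment heats aliquots of the same extract to a ladder of
temperatures and quantifies what stays soluble.  Every table in this package is
keyed by *sample labels* of the form ``condition_replicate_temperature``
(e.g. ``vehicle_1_37``), one column per aliquot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: The study's temperature ladder (°C): 37 is the reference temperature T_min.
DEFAULT_TEMPERATURES = (37.0, 42.0, 47.0, 52.0, 57.0, 62.0, 67.0)

VEHICLE = "vehicle"
COMPOUND = "compound"


def _fmt_temp(t: float) -> str:
    return f"{t:g}"


@dataclass(frozen=True)
class TemperatureGradient:
    """Strictly increasing ladder of incubation temperatures in °C."""

    temps: tuple[float, ...] = DEFAULT_TEMPERATURES

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.temps)
        if len(temps) < 4:
            raise ValueError("gradient needs at least 4 temperatures")
        if any(t2 <= t1 for t1, t2 in zip(temps, temps[1:])):
            raise ValueError("gradient temperatures must be strictly increasing")
        if temps[0] <= 0:
            raise ValueError("temperatures must be positive (°C, above absolute zero)")
        object.__setattr__(self, "temps", temps)

    @property
    def t_min(self) -> float:
        return self.temps[0]

    @property
    def t_max(self) -> float:
        return self.temps[-1]

    @property
    def span(self) -> tuple[float, float]:
        return (self.t_min, self.t_max)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.temps, dtype=float)

    def __len__(self) -> int:
        return len(self.temps)

    def __iter__(self) -> Iterator[float]:
        return iter(self.temps)


@dataclass(frozen=True)
class ExperimentDesign:
    """Two-condition (vehicle vs compound) replicated thermal-shift design.

    An *experiment* is one (condition, replicate) pair: it contributes one
    column per gradient temperature.
    """

    gradient: TemperatureGradient = field(default_factory=TemperatureGradient)
    conditions: tuple[str, str] = (VEHICLE, COMPOUND)
    replicates: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise ValueError("design requires exactly two conditions")
        if len(set(self.conditions)) != 2:
            raise ValueError("conditions must be distinct")
        if len(self.replicates) < 1:
            raise ValueError("at least one replicate required")

    @property
    def vehicle(self) -> str:
        return self.conditions[0]

    @property
    def treatment(self) -> str:
        return self.conditions[1]

    def experiments(self) -> list[tuple[str, int]]:
        """All (condition, replicate) pairs, vehicle first, replicates in order."""
        return [(c, r) for c in self.conditions for r in self.replicates]

    def sample_label(self, condition: str, replicate: int, temperature: float) -> str:
        if condition not in self.conditions:
            raise ValueError(f"unknown condition {condition!r}")
        return f"{condition}_{replicate}_{_fmt_temp(temperature)}"

    def sample_labels(self) -> list[str]:
        """Column order: by condition, then replicate, then temperature."""
        return [
            self.sample_label(c, r, t)
            for c, r in self.experiments()
            for t in self.gradient
        ]

    def experiment_labels(self, condition: str, replicate: int) -> list[str]:
        return [self.sample_label(condition, replicate, t) for t in self.gradient]


def parse_sample_label(label: str) -> tuple[str, int, float]:
    """Split ``condition_replicate_temperature`` into its parts.

    The condition itself may contain underscores; replicate and temperature
    are taken from the right.
    """
    parts = label.rsplit("_", 2)
    if len(parts) != 3:
        raise ValueError(f"malformed sample label {label!r}")
    condition, rep, temp = parts
    try:
        return condition, int(rep), float(temp)
    except ValueError as exc:
        raise ValueError(f"malformed sample label {label!r}") from exc


def design_from_columns(columns: Sequence[str]) -> ExperimentDesign:
    """Reconstruct the design implied by a table's sample columns."""
    conditions: list[str] = []
    replicates: list[int] = []
    temps: list[float] = []
    for col in columns:
        c, r, t = parse_sample_label(col)
        if c not in conditions:
            conditions.append(c)
        if r not in replicates:
            replicates.append(r)
        if t not in temps:
            temps.append(t)
    if len(conditions) != 2:
        raise ValueError(
            f"expected exactly two conditions in columns, found {conditions}"
        )
    gradient = TemperatureGradient(tuple(sorted(temps)))
    design = ExperimentDesign(
        gradient=gradient,
        conditions=(conditions[0], conditions[1]),
        replicates=tuple(sorted(replicates)),
    )
    expected = set(design.sample_labels())
    missing = expected.difference(columns)
    if missing:
        raise ValueError(f"design incomplete: missing sample columns {sorted(missing)}")
    return design
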