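"""Pressure protocols of the dynamic loading rig.

The rig presses a shaft of known mass onto the sensor face periodically; the
cadence (steps/min) sets the cycle period.  Three protocol families are
generated here as :class:`~insolekit.sensor_model.PressureTrace` objects:

* ``staircase``  - square-wave blocks at increasing masses (calibration),
* ``periodic``   - constant-amplitude square wave (frequency sweeps,
  durability runs),
* ``ramp_cycles``- quasi-static triangular loading/unloading ramps
  (hysteresis loops).

Square cycles are laid out as quarter-period rest, half-period load,
quarter-period rest so every trace starts and ends at zero pressure while
keeping a 50% duty cycle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ConfigurationError, PressureRangeError
from .sensor_model import DEFAULT_DIAMETER, DEFAULT_P_MAX, PressureTrace, mass_to_pressure

__all__ = [
    "CADENCE_RANGE",
    "DEFAULT_STAIRCASE_MASSES",
    "LoadingProtocol",
    "staircase_protocol",
    "periodic_loading",
    "ramp_cycle",
]

#: Cadence range the rig was operated over, steps/min.
CADENCE_RANGE = (30.0, 70.0)

#: Default calibration staircase: 0.7 kg shaft plus 1.0 kg increments up to
#: 14.7 kg -- fifteen levels spanning 41.5 to 872.4 kPa in 59.35 kPa steps.
DEFAULT_STAIRCASE_MASSES = tuple(round(0.7 + k, 1) for k in range(15))

MAX_MASS_KG = 14.7


@dataclass
class LoadingProtocol:
    """Declarative description of a rig protocol (JSON-serializable)."""

    kind: str  # staircase | periodic | ramp_cycles
    levels: list = field(default_factory=list)  # masses (kg) or pressures (kPa)
    levels_unit: str = "kg"
    steps_per_min: float = 40.0
    duration_per_level: float = 60.0
    n_cycles: int = 3
    sample_rate: float = 1000.0
    diameter: float = DEFAULT_DIAMETER
    ramp_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("staircase", "periodic", "ramp_cycles"):
            raise ConfigurationError(f"unknown protocol kind {self.kind!r}")
        if self.levels_unit not in ("kg", "kPa"):
            raise ConfigurationError("levels_unit must be 'kg' or 'kPa'")
        if self.levels_unit == "kg" and any(m < 0 or m > MAX_MASS_KG for m in self.levels):
            raise ConfigurationError(f"masses must lie in [0, {MAX_MASS_KG}] kg")

    @property
    def period(self) -> float:
        """Cycle period in s."""
        return 60.0 / self.steps_per_min

    def level_pressures(self) -> np.ndarray:
        """Peak pressure of each level in kPa."""
        if self.levels_unit == "kg":
            return np.array([mass_to_pressure(m, self.diameter) for m in self.levels])
        return np.asarray(self.levels, dtype=float)

    def to_json(self, path) -> None:
        payload = {"schema_version": 1, **asdict(self)}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LoadingProtocol":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        payload.pop("schema_version", None)
        return cls(**payload)


def _check_cadence(steps_per_min: float) -> None:
    lo, hi = CADENCE_RANGE
    if not (lo <= steps_per_min <= hi):
        warnings.warn(
            f"cadence {steps_per_min} steps/min outside the tested range "
            f"{lo:.0f}-{hi:.0f}; trace generated anyway",
            stacklevel=3,
        )


def _square_cycle(peak_kpa: float, period: float, sample_rate: float) -> np.ndarray:
    """One rest/load/rest square cycle: zero on the outer quarters, ``peak``
    on the middle half of the period."""
    n = int(round(period * sample_rate))
    t = np.arange(n) / sample_rate
    vals = np.zeros(n)
    vals[(t >= period / 4) & (t < 3 * period / 4)] = peak_kpa
    return vals


def staircase_protocol(
    masses=DEFAULT_STAIRCASE_MASSES,
    steps_per_min: float = 40.0,
    duration_per_level: float = 60.0,
    diameter: float = DEFAULT_DIAMETER,
    sample_rate: float = 1000.0,
) -> PressureTrace:
    """Concatenated square-wave blocks, one per mass, ascending.

    Each block lasts ``duration_per_level`` seconds, which must be a whole
    number of cycle periods.
    """
    masses = list(masses)
    if masses != sorted(masses):
        raise ConfigurationError("masses must be sorted ascending")
    _check_cadence(steps_per_min)
    period = 60.0 / steps_per_min
    n_cycles = duration_per_level / period
    if abs(n_cycles - round(n_cycles)) > 1e-9:
        raise ConfigurationError(
            f"duration_per_level ({duration_per_level} s) is not a whole number "
            f"of {period} s cycles"
        )
    n_cycles = int(round(n_cycles))
    blocks = []
    for m in masses:
        peak = mass_to_pressure(m, diameter)
        cycle = _square_cycle(peak, period, sample_rate)
        blocks.append(np.tile(cycle, n_cycles))
    values = np.concatenate(blocks) if blocks else np.zeros(0)
    return PressureTrace(sample_rate, values)


def periodic_loading(
    pressure: float,
    steps_per_min: float = 40.0,
    n_cycles: int = 1,
    sample_rate: float = 1000.0,
) -> PressureTrace:
    """Square wave of ``n_cycles`` periods at a fixed peak pressure."""
    if n_cycles <= 0:
        raise ConfigurationError(f"n_cycles must be positive, got {n_cycles!r}")
    if pressure > DEFAULT_P_MAX:
        raise PressureRangeError(f"pressure {pressure} kPa exceeds the working range")
    _check_cadence(steps_per_min)
    period = 60.0 / steps_per_min
    cycle = _square_cycle(pressure, period, sample_rate)
    return PressureTrace(sample_rate, np.tile(cycle, n_cycles))


def ramp_cycle(
    p_max: float,
    n_cycles: int = 3,
    sample_rate: float = 1000.0,
    ramp_duration: float = 1.0,
) -> PressureTrace:
    """Symmetric triangular ramps 0 -> p_max -> 0, repeated ``n_cycles`` times.

    The peak sample is hit exactly once per cycle; a final zero sample closes
    the trace.
    """
    if p_max > DEFAULT_P_MAX:
        raise PressureRangeError(f"p_max {p_max} kPa exceeds the working range")
    if n_cycles <= 0:
        raise ConfigurationError(f"n_cycles must be positive, got {n_cycles!r}")
    n_half = int(round(ramp_duration * sample_rate))
    up = np.linspace(0.0, p_max, n_half, endpoint=False)
    down = np.linspace(p_max, 0.0, n_half, endpoint=False)
    cycle = np.concatenate([up, down])
    values = np.concatenate([np.tile(cycle, n_cycles), [0.0]])
    return PressureTrace(sample_rate, values)
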