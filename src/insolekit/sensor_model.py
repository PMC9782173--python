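"""Physics and signal model of a single capacitive pressure sensor.

The sensor is a parallel-plate capacitor with a two-layer dielectric (air
cavity over a flexible polymer film).  Three ingredients make up the forward
model used throughout the package:

* a static, linear pressure -> relative-capacitance transduction with slope
  ``S`` (MPa^-1), plus a quadratic hysteresis bump on the unloading branch;
* an asymmetric first-order lag describing response/recovery dynamics;
* optional additive Gaussian noise on the relative capacitance.

Units are SI internally except pressures, which are carried in kPa in traces
and converted to MPa where the sensitivity slope applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, FormatError, GeometryError, PressureRangeError

__all__ = [
    "EPSILON_0",
    "GRAVITY",
    "DielectricStack",
    "SensorSpec",
    "PressureTrace",
    "CapacitanceTrace",
    "circular_area",
    "series_capacitance",
    "mass_to_pressure",
    "static_response",
    "hysteretic_response",
    "apply_dynamics",
    "simulate_capacitance_trace",
]

#: Vacuum permittivity, F/m.
EPSILON_0 = 8.854e-12

#: Gravitational acceleration used for mass -> pressure conversion, m/s^2.
#: 9.8 (not 9.81) reproduces both printed rig conversions exactly:
#: 0.7 kg -> 41.5 kPa and 14.7 kg -> 872.4 kPa on the 14.5 mm face.
GRAVITY = 9.8

#: Default sensor face diameter, m.
DEFAULT_DIAMETER = 14.5e-3

#: Default working range, kPa (rig shaft weight .. maximum disk load).
DEFAULT_P_MIN = 41.5
DEFAULT_P_MAX = 872.4

#: Degree of hysteresis (percent) the default loop is calibrated to.
DEFAULT_DH_PERCENT = 9.8

#: Slack on range checks, kPa: the nominal 872.4 kPa bound is a rounded
#: value, 14.7 kg actually converts to 872.4038 kPa.
RANGE_TOL_KPA = 0.01

_LN9 = math.log(9.0)

#: Default time constants, s: chosen so that the 10-90% rise interval is
#: 142 ms and the 90-10% fall interval is 160 ms (t = tau * ln 9).
DEFAULT_TAU_RISE = 0.142 / _LN9
DEFAULT_TAU_FALL = 0.160 / _LN9


def circular_area(diameter: float) -> float:
    """Area in m^2 of a circular face of the given diameter in m."""
    if diameter <= 0:
        raise GeometryError(f"diameter must be positive, got {diameter!r}")
    return math.pi * (diameter / 2.0) ** 2


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DielectricStack:
    """Two stacked dielectric layers between parallel plates.

    Parameters
    ----------
    plate_area : float
        Plate area in m^2.
    d1, d2 : float
        Layer thicknesses in m.  One may be zero (single-dielectric limit)
        but not both.
    k1, k2 : float
        Relative permittivities (>= 1).
    """

    plate_area: float
    d1: float
    k1: float
    d2: float
    k2: float

    def __post_init__(self) -> None:
        if self.plate_area <= 0:
            raise GeometryError(f"plate_area must be > 0, got {self.plate_area!r}")
        if self.d1 < 0 or self.d2 < 0:
            raise GeometryError("layer thicknesses must be non-negative")
        if self.d1 + self.d2 <= 0:
            raise GeometryError("total dielectric thickness must be > 0")
        if self.k1 < 1 or self.k2 < 1:
            raise GeometryError("relative permittivities must be >= 1")


def _default_stack() -> DielectricStack:
    # 1.0 mm air cavity over a 0.2 mm flexible polymer film; k2 = 4.2 is a
    # typical thermoplastic-polyurethane permittivity (not measured).
    return DielectricStack(
        plate_area=circular_area(DEFAULT_DIAMETER), d1=1.0e-3, k1=1.0, d2=0.2e-3, k2=4.2
    )


@dataclass(frozen=True)
class SensorSpec:
    """Full parameterization of one capacitive pressure sensor.

    ``S`` is the transduction slope in MPa^-1 ((dC/C0) per MPa); ``alpha``
    shapes the unloading-branch hysteresis bump (MPa^-2).  ``C0`` defaults to
    the series capacitance of ``stack``.
    """

    diameter: float = DEFAULT_DIAMETER
    stack: DielectricStack = field(default_factory=_default_stack)
    C0: float | None = None
    S: float = 1.19
    alpha: float | None = None
    tau_rise: float = DEFAULT_TAU_RISE
    tau_fall: float = DEFAULT_TAU_FALL
    p_min: float = DEFAULT_P_MIN
    p_max: float = DEFAULT_P_MAX

    def __post_init__(self) -> None:
        if self.C0 is None:
            object.__setattr__(self, "C0", series_capacitance(self.stack))
        if self.alpha is None:
            object.__setattr__(self, "alpha", alpha_for_dh(self.S, DEFAULT_DH_PERCENT, self.p_max))
        if self.S <= 0:
            raise PressureRangeError("sensitivity S must be > 0")
        if self.alpha < 0:
            raise PressureRangeError("alpha must be >= 0")
        if self.tau_rise <= 0 or self.tau_fall <= 0:
            raise PressureRangeError("time constants must be > 0")
        if not (0 <= self.p_min < self.p_max):
            raise PressureRangeError("need 0 <= p_min < p_max")
        if self.C0 <= 0:
            raise GeometryError("C0 must be > 0")

    @classmethod
    def out_of_insole(cls, **overrides) -> "SensorSpec":
        """Default bare-sensor profile: S = 1.19 MPa^-1."""
        return cls(S=overrides.pop("S", 1.19), **overrides)

    @classmethod
    def in_insole(cls, **overrides) -> "SensorSpec":
        """Default in-insole profile: S = 0.55 MPa^-1 (sensitivity attenuated
        by the insole casing)."""
        return cls(S=overrides.pop("S", 0.55), **overrides)

    def with_(self, **changes) -> "SensorSpec":
        return replace(self, **changes)


def alpha_for_dh(S: float, dh_percent: float, p_max_kpa: float) -> float:
    """Bump coefficient producing a given degree of hysteresis.

    For the quadratic-bump loop the degree of hysteresis has the closed form
    ``DH = 100 * alpha * p_max / (3 * S)`` (pressures in MPa), so
    ``alpha = 3 * S * (DH/100) / p_max``.
    """
    return 3.0 * S * (dh_percent / 100.0) / (p_max_kpa * 1e-3)


class _Trace:
    """Shared behaviour of uniformly sampled single-channel traces."""

    sample_rate: float
    values: np.ndarray
    start_time: float

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.sample_rate


@dataclass
class PressureTrace(_Trace):
    """Uniformly sampled pressure time series in kPa."""

    sample_rate: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be > 0")
        if self.values.size and (not np.all(np.isfinite(self.values)) or self.values.min() < 0):
            raise FormatError("pressure values must be finite and >= 0")


@dataclass
class CapacitanceTrace(_Trace):
    """Uniformly sampled capacitance time series.

    ``units`` is ``"F"`` for absolute capacitance or ``"relative"`` for the
    dimensionless relative change (C - C0)/C0.
    """

    sample_rate: float
    values: np.ndarray
    start_time: float = 0.0
    units: str = "F"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be > 0")
        if self.units not in ("F", "relative"):
            raise FormatError(f"units must be 'F' or 'relative', got {self.units!r}")
        if self.values.size:
            if not np.all(np.isfinite(self.values)):
                raise FormatError("capacitance values must be finite")
            if self.units == "relative" and self.values.min() < -1.0:
                raise FormatError("relative change cannot go below -1")


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def series_capacitance(stack: DielectricStack) -> float:
    """Capacitance in F of two dielectric layers in series.

    ``C = eps0 * A / (d1/k1 + d2/k2)``.  Strictly increasing in area and
    permittivities, strictly decreasing in the layer thicknesses.
    """
    gap = stack.d1 / stack.k1 + stack.d2 / stack.k2
    if gap <= 0:
        raise GeometryError("effective gap d1/k1 + d2/k2 must be > 0")
    return EPSILON_0 * stack.plate_area / gap


def mass_to_pressure(mass: float, diameter: float = DEFAULT_DIAMETER) -> float:
    """Pressure in kPa exerted by ``mass`` kg resting on a circular face.

    Uses g = 9.8 m/s^2 (see :data:`GRAVITY`).
    """
    if mass < 0:
        raise PressureRangeError(f"mass must be >= 0, got {mass!r}")
    return mass * GRAVITY / circular_area(diameter) / 1000.0


def static_response(
    pressure,
    spec: SensorSpec,
    branch: str = "loading",
    p_max_branch: float | None = None,
):
    """Quasi-static relative capacitance change dC/C0 at a given pressure.

    Parameters
    ----------
    pressure : float or array
        Applied pressure in kPa, within ``[0, spec.p_max]``.
    branch : {"loading", "unloading"}
        The unloading branch adds the hysteresis bump
        ``alpha * P * (p_max_branch - P)`` (pressures in MPa) and therefore
        lies on or above the loading branch; the two branches agree at P = 0
        and at the cycle turning point ``p_max_branch``.
    p_max_branch : float
        Turning-point pressure of the current cycle in kPa (required for the
        unloading branch).
    """
    p = np.asarray(pressure, dtype=float)
    if np.any(p < 0) or np.any(p > spec.p_max + RANGE_TOL_KPA):
        raise PressureRangeError(
            f"pressure outside working range [0, {spec.p_max}] kPa"
        )
    P = p * 1e-3  # MPa
    out = spec.S * P
    if branch == "unloading":
        if p_max_branch is None:
            raise PressureRangeError("unloading branch requires p_max_branch")
        Pm = p_max_branch * 1e-3
        out = out + spec.alpha * P * np.maximum(Pm - P, 0.0)
    elif branch != "loading":
        raise ValueError(f"branch must be 'loading' or 'unloading', got {branch!r}")
    if np.isscalar(pressure):
        return float(out)
    return out


def hysteretic_response(pressure: np.ndarray, spec: SensorSpec) -> np.ndarray:
    """Static hysteretic response of a whole pressure trace (kPa -> dC/C0).

    Branch tracking: samples arriving on a rising segment follow the loading
    branch; once the signal turns down, the unloading branch is used with the
    last local maximum as the cycle turning point.  Both branches coincide at
    the turning point and at zero pressure, so full loading/unloading cycles
    are continuous.
    """
    p = np.asarray(pressure, dtype=float)
    n = p.size
    if n == 0:
        return np.zeros(0)
    if np.any(p < 0) or np.any(p > spec.p_max + RANGE_TOL_KPA):
        raise PressureRangeError(f"pressure outside working range [0, {spec.p_max}] kPa")

    step = np.sign(np.diff(p))  # step[t-1] = direction of arrival at sample t
    t = np.arange(1, n)
    nz = step != 0
    last_move = np.maximum.accumulate(np.where(nz, t, 0))
    state = np.ones(n)  # +1 loading, -1 unloading
    state[1:] = np.where(last_move > 0, step[np.maximum(last_move - 1, 0)], 1.0)

    # turning points: first sample of each falling run that follows a rise
    trans = (state[1:] == -1.0) & (state[:-1] == 1.0)
    last_turn = np.maximum.accumulate(np.where(trans, t, 0))
    p_turn = np.where(last_turn > 0, p[np.maximum(last_turn - 1, 0)], 0.0)

    P = p * 1e-3
    out = spec.S * P
    Pm = np.zeros(n)
    Pm[1:] = p_turn * 1e-3
    unload = state == -1.0
    out[unload] += spec.alpha * P[unload] * np.maximum(Pm[unload] - P[unload], 0.0)
    return out


def _first_order_lag(x: np.ndarray, dt: float, tau_rise: float, tau_fall: float) -> np.ndarray:
    """Discrete asymmetric first-order lag, exact exponential update.

    ``dy/dt = (x - y)/tau`` with tau = tau_rise while x > y, tau_fall while
    x < y.  For piecewise-constant input the update is exact.
    """
    a_r = 1.0 - math.exp(-dt / tau_rise)
    a_f = 1.0 - math.exp(-dt / tau_fall)
    y = np.empty_like(x)
    xl = x.tolist()
    cur = xl[0] if len(xl) else 0.0
    out = y  # local alias
    for i, xi in enumerate(xl):
        if xi > cur:
            cur += (xi - cur) * a_r
        elif xi < cur:
            cur += (xi - cur) * a_f
        out[i] = cur
    return y


def apply_dynamics(target, spec: SensorSpec, sample_rate: float | None = None):
    """First-order response dynamics applied to a trace or raw array.

    Accepts a :class:`PressureTrace`, a relative :class:`CapacitanceTrace` or
    a plain array (``sample_rate`` then required).  The output is bounded by
    the input extrema and converges to the input at steady state.
    """
    if isinstance(target, PressureTrace):
        y = _first_order_lag(target.values, 1.0 / target.sample_rate, spec.tau_rise, spec.tau_fall)
        return PressureTrace(target.sample_rate, y, target.start_time)
    if isinstance(target, CapacitanceTrace):
        y = _first_order_lag(target.values, 1.0 / target.sample_rate, spec.tau_rise, spec.tau_fall)
        return CapacitanceTrace(target.sample_rate, y, target.start_time, target.units)
    if sample_rate is None:
        raise FormatError("sample_rate required when passing a raw array")
    return _first_order_lag(np.asarray(target, dtype=float), 1.0 / sample_rate, spec.tau_rise, spec.tau_fall)


def simulate_capacitance_trace(
    pressure: PressureTrace,
    spec: SensorSpec,
    noise_sd: float = 0.01,
    seed: int | np.random.SeedSequence | None = None,
) -> CapacitanceTrace:
    """Simulate the acquired capacitance signal for a pressure protocol.

    Composes the static hysteretic transduction, the first-order dynamics and
    additive Gaussian noise (sd in relative units) and returns the absolute
    capacitance ``C0 * (1 + response + noise)``.  Deterministic for a fixed
    seed; ``noise_sd = 0`` gives the noiseless model exactly.
    """
    resp = hysteretic_response(pressure.values, spec)
    dyn = _first_order_lag(resp, 1.0 / pressure.sample_rate, spec.tau_rise, spec.tau_fall)
    if noise_sd < 0:
        raise PressureRangeError("noise_sd must be >= 0")
    if noise_sd > 0:
        if seed is None:
            raise ConfigurationError("a seed is required for noisy simulation")
        rng = np.random.default_rng(seed)
        dyn = dyn + rng.normal(0.0, noise_sd, size=dyn.size)
    values = spec.C0 * (1.0 + dyn)
    return CapacitanceTrace(pressure.sample_rate, values, pressure.start_time, units="F")
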