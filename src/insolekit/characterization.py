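"""Sensor-performance metrics computed from capacitance/pressure traces.

Implements the full single-sensor characterization suite: staircase cycle
amplitudes, sensitivity/linearity fit, degree of hysteresis, 10-90% response
and 90-10% recovery times, loading-frequency invariance and long-run
baseline/peak drift.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .errors import (
    FitError,
    InsufficientDataError,
    NoEdgeError,
    UndefinedHysteresisError,
)
from .rig_simulator import DEFAULT_STAIRCASE_MASSES, LoadingProtocol, staircase_protocol
from .sensor_model import (
    CapacitanceTrace,
    SensorSpec,
    simulate_capacitance_trace,
    static_response,
)

__all__ = [
    "HysteresisLoop",
    "CharacterizationReport",
    "FitResult",
    "extract_cycle_amplitudes",
    "fit_sensitivity",
    "degree_of_hysteresis",
    "default_hysteresis_loop",
    "hysteresis_loop_from_trace",
    "response_recovery_times",
    "frequency_invariance",
    "durability_drift",
    "sensitivity_study",
]


@dataclass
class HysteresisLoop:
    """Loading/unloading response pair sampled on a common pressure grid."""

    pressures: np.ndarray  # kPa, strictly increasing
    loading_values: np.ndarray
    unloading_values: np.ndarray

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.loading_values = np.asarray(self.loading_values, dtype=float)
        self.unloading_values = np.asarray(self.unloading_values, dtype=float)
        if not (len(self.pressures) == len(self.loading_values) == len(self.unloading_values)):
            raise InsufficientDataError("loop arrays must have equal length")
        if len(self.pressures) < 2:
            raise InsufficientDataError("loop needs at least 2 grid points")
        if np.any(np.diff(self.pressures) <= 0):
            raise InsufficientDataError("pressure grid must be strictly increasing")


@dataclass
class FitResult:
    slope: float
    intercept: float
    stderr: float
    r_squared: float


@dataclass
class CharacterizationReport:
    """Aggregated headline metrics of one characterization run."""

    slope: float | None = None  # MPa^-1
    slope_stderr: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    dh_percent: float | None = None
    response_time: float | None = None  # s
    recovery_time: float | None = None  # s
    freq_invariance: float | None = None
    drift_c0: float | None = None
    drift_cf: float | None = None

    def __post_init__(self) -> None:
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise FitError("r_squared must lie in [0, 1]")
        for name in ("response_time", "recovery_time"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise NoEdgeError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {"schema_version": 1, **asdict(self)}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _relative_values(trace: CapacitanceTrace, n_baseline: int) -> tuple[np.ndarray, float]:
    """Values and the divisor C0 so that (peak - base)/C0 is dC/C0."""
    if trace.units == "relative":
        return trace.values, 1.0
    c0 = float(np.mean(trace.values[:n_baseline]))
    if c0 <= 0:
        raise InsufficientDataError("cannot establish a positive pre-protocol baseline C0")
    return trace.values, c0


def extract_cycle_amplitudes(
    trace: CapacitanceTrace, protocol: LoadingProtocol
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level mean cycle amplitude dC/C0 of a staircase recording.

    For every pressure level the amplitude of each cycle is (cycle max -
    cycle baseline)/C0, the baseline being the local pre-load minimum (the
    first quarter of the cycle is unloaded by construction), which makes the
    analysis robust to slow drift.  The first cycle of each level is
    discarded as transient and C0 is the pre-protocol baseline.

    Returns
    -------
    (pressures_kpa, amplitudes) : per-level arrays.
    """
    fs = trace.sample_rate
    period = protocol.period
    spc = int(round(period * fs))  # samples per cycle
    cycles_per_level = int(round(protocol.duration_per_level / period))
    if cycles_per_level < 2:
        raise InsufficientDataError("need at least 2 cycles per level (first is discarded)")
    n_levels = len(protocol.levels)
    if len(trace) < n_levels * cycles_per_level * spc:
        raise InsufficientDataError("trace shorter than the protocol it claims to follow")
    quarter = max(1, spc // 4)
    values, c0 = _relative_values(trace, quarter)

    amplitudes = np.empty(n_levels)
    for lvl in range(n_levels):
        amps = []
        for cyc in range(1, cycles_per_level):
            start = (lvl * cycles_per_level + cyc) * spc
            seg = values[start : start + spc]
            baseline = float(np.min(seg[:quarter]))
            amps.append((float(np.max(seg)) - baseline) / c0)
        amplitudes[lvl] = np.mean(amps)
    return protocol.level_pressures(), amplitudes


def fit_sensitivity(pressures_mpa, amplitudes) -> FitResult:
    """Ordinary least-squares line through (pressure, dC/C0) points.

    The slope is the sensitivity in MPa^-1 when pressures are given in MPa.
    """
    x = np.asarray(pressures_mpa, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need at least 3 points for a sensitivity fit")
    if np.ptp(x) == 0:
        raise FitError("degenerate fit: zero variance in pressure")
    res = stats.linregress(x, y)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
    )


def degree_of_hysteresis(loop: HysteresisLoop) -> float:
    """Degree of hysteresis in percent.

    ``DH = 100 * (A_unloading - A_loading) / A_loading`` with both areas
    obtained by trapezoidal integration over the common pressure grid.  The
    sign is preserved (a loop with the unloading branch below the loading one
    yields a negative DH).
    """
    a_load = float(np.trapezoid(loop.loading_values, loop.pressures))
    a_unload = float(np.trapezoid(loop.unloading_values, loop.pressures))
    if a_load == 0:
        raise UndefinedHysteresisError("loading-curve area is zero; DH undefined")
    return 100.0 * (a_unload - a_load) / a_load


def default_hysteresis_loop(spec: SensorSpec | None = None, n_points: int = 1000) -> HysteresisLoop:
    """Quasi-static branch pair of ``spec`` over [0, p_max] on a uniform grid."""
    spec = spec or SensorSpec.out_of_insole()
    grid = np.linspace(0.0, spec.p_max, n_points)
    loading = static_response(grid, spec, branch="loading")
    unloading = static_response(grid, spec, branch="unloading", p_max_branch=spec.p_max)
    return HysteresisLoop(grid, loading, unloading)


def hysteresis_loop_from_trace(
    trace: CapacitanceTrace, protocol: LoadingProtocol, n_grid: int = 200
) -> HysteresisLoop:
    """Reconstruct the loading/unloading branch pair from a ramp recording.

    Assumes the trace follows a ``ramp_cycles`` protocol: each cycle is half
    a linear ramp up to the peak pressure and half a ramp down.  Branches
    are interpolated onto a common pressure grid and averaged over cycles.
    The reconstruction is quasi-static -- slow ramps (duration >> sensor
    time constants) keep the dynamic lag from inflating the loop.
    """
    if protocol.kind != "ramp_cycles":
        raise InsufficientDataError("loop reconstruction needs a ramp_cycles protocol")
    fs = trace.sample_rate
    half = int(round(protocol.ramp_duration * fs))
    spc = 2 * half
    if len(trace) < protocol.n_cycles * spc:
        raise InsufficientDataError("trace shorter than the ramp protocol")
    values, c0 = _relative_values(trace, max(1, half // 50))
    rel = values / c0 - 1.0 if trace.units == "F" else values
    p_max = float(protocol.level_pressures().max()) if protocol.levels else None
    if p_max is None:
        raise InsufficientDataError("ramp protocol must declare its peak pressure level")
    p_up = np.linspace(0.0, p_max, half, endpoint=False)
    p_down = np.linspace(p_max, 0.0, half, endpoint=False)
    grid = np.linspace(0.0, p_max, n_grid)
    loading = np.zeros(n_grid)
    unloading = np.zeros(n_grid)
    for cyc in range(protocol.n_cycles):
        seg = rel[cyc * spc : (cyc + 1) * spc]
        loading += np.interp(grid, p_up, seg[:half])
        unloading += np.interp(grid, p_down[::-1], seg[half:][::-1])
    loading /= protocol.n_cycles
    unloading /= protocol.n_cycles
    return HysteresisLoop(grid, loading, unloading)


def _crossings(x: np.ndarray, threshold: float, fs: float, direction: str) -> list[float]:
    """Linearly interpolated threshold-crossing times (first crossing wins on
    ties)."""
    if direction == "up":
        hit = (x[:-1] < threshold) & (x[1:] >= threshold)
    else:
        hit = (x[:-1] > threshold) & (x[1:] <= threshold)
    idx = np.nonzero(hit)[0]
    times = []
    for i in idx:
        frac = (threshold - x[i]) / (x[i + 1] - x[i])
        times.append((i + frac) / fs)
    return times


def response_recovery_times(
    trace: CapacitanceTrace, sample_rate: float | None = None
) -> tuple[float, float]:
    """10-90% rise and 90-10% fall intervals in seconds.

    Thresholds are relative to the trace extrema, so the estimator is
    invariant to the absolute signal scale.  If several qualifying edges are
    present the intervals are averaged.
    """
    if isinstance(trace, CapacitanceTrace):
        x = trace.values
        fs = trace.sample_rate
    else:
        x = np.asarray(trace, dtype=float)
        if sample_rate is None:
            raise InsufficientDataError("sample_rate required for raw arrays")
        fs = sample_rate
    if x.size < 2 or np.ptp(x) <= 0:
        raise NoEdgeError("trace has no dynamic range; no edges to measure")
    lo, hi = float(x.min()), float(x.max())
    t10 = lo + 0.1 * (hi - lo)
    t90 = lo + 0.9 * (hi - lo)

    def _pair(starts: list[float], ends: list[float]) -> list[float]:
        intervals, j = [], 0
        for t0 in starts:
            while j < len(ends) and ends[j] <= t0:
                j += 1
            if j == len(ends):
                break
            intervals.append(ends[j] - t0)
            j += 1
        return intervals

    rises = _pair(_crossings(x, t10, fs, "up"), _crossings(x, t90, fs, "up"))
    falls = _pair(_crossings(x, t90, fs, "down"), _crossings(x, t10, fs, "down"))
    if not rises or not falls:
        raise NoEdgeError("no full rising and falling edge found")
    return float(np.mean(rises)), float(np.mean(falls))


def _steady_cycle_amplitude(trace: CapacitanceTrace) -> float:
    """Mean (cycle max - cycle min) over all cycles but the first.

    Cycle boundaries are detected from the trace itself (mid-level rising
    edges), so the measurement does not depend on a nominal cadence and
    identical traces always yield identical amplitudes.
    """
    x = trace.values
    if x.size < 4 or np.ptp(x) <= 0:
        raise InsufficientDataError("trace has no cycles to measure")
    # mid-level between the steady trough and plateau populations; quantiles
    # rather than extrema so a deep startup transient cannot skew it
    lo, hi = np.quantile(x, [0.1, 0.9])
    mid = 0.5 * (lo + hi)
    edges = np.nonzero((x[:-1] < mid) & (x[1:] >= mid))[0]
    if edges.size < 3:
        raise InsufficientDataError("need at least 2 full cycles to measure a steady amplitude")
    amps = []
    for a, b in zip(edges[1:-1], edges[2:]):  # discard the first cycle
        seg = x[a:b]
        amps.append(float(seg.max()) - float(seg.min()))
    return float(np.mean(amps))


def frequency_invariance(traces: dict) -> float:
    """Maximum relative deviation of the steady-cycle amplitude across
    cadences.

    ``traces`` maps cadence (steps/min) to the trace recorded at that
    cadence, all at the same peak pressure.  Returns
    ``max_i |dC_i - mean| / mean``.
    """
    if len(traces) < 2:
        raise InsufficientDataError("need at least two cadences to compare")
    amps = np.array(
        [_steady_cycle_amplitude(tr) for _, tr in sorted(traces.items())]
    )
    mean = amps.mean()
    if mean == 0:
        raise InsufficientDataError("zero mean amplitude; invariance undefined")
    return float(np.max(np.abs(amps - mean)) / mean)


def durability_drift(trace: CapacitanceTrace, window: float) -> tuple[float, float]:
    """Relative drift of the cycle baseline (C0) and peak (Cf).

    Compares the first and last ``window`` seconds of a long periodic
    recording: within each window the baseline is the mean of the lowest
    decile of samples and the peak the mean of the highest decile, so no
    cycle bookkeeping is required.  Returns ``(c0_drift, cf_drift)`` as
    relative differences (last - first)/first.
    """
    fs = trace.sample_rate
    nw = int(round(window * fs))
    if len(trace) < 2 * nw or nw < 10:
        raise InsufficientDataError("trace must cover at least two analysis windows")

    def _levels(seg: np.ndarray) -> tuple[float, float]:
        lo_thr, hi_thr = np.quantile(seg, [0.1, 0.9])
        return float(seg[seg <= lo_thr].mean()), float(seg[seg >= hi_thr].mean())

    b_first, p_first = _levels(trace.values[:nw])
    b_last, p_last = _levels(trace.values[-nw:])
    if b_first == 0 or p_first == 0:
        raise InsufficientDataError("zero reference level; relative drift undefined")
    return (b_last - b_first) / b_first, (p_last - p_first) / p_first


def sensitivity_study(
    n_sensors: int = 16,
    mean_s: float = 1.19,
    inter_sensor_sd: float = 0.12,
    noise_sd: float = 0.01,
    seed: int = 0,
    steps_per_min: float = 40.0,
    duration_per_level: float = 15.0,
    sample_rate: float = 200.0,
) -> dict:
    """Noisy staircase calibration of a batch of simulated sensors.

    Each sensor draws its true sensitivity from N(mean_s, inter_sensor_sd^2)
    (truncated at 0.1), runs the default staircase with measurement noise and
    is fitted individually.  Returns per-sensor true/fitted slopes and R^2,
    plus the batch mean slope and its standard error -- the sensor-to-sensor
    scatter is what dominates the uncertainty of the batch average.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    true_s = np.maximum(rng.normal(mean_s, inter_sensor_sd, n_sensors), 0.1)
    protocol = LoadingProtocol(
        kind="staircase",
        levels=list(DEFAULT_STAIRCASE_MASSES),
        steps_per_min=steps_per_min,
        duration_per_level=duration_per_level,
        sample_rate=sample_rate,
    )
    pressure = staircase_protocol(
        protocol.levels, steps_per_min, duration_per_level, sample_rate=sample_rate
    )
    child_seeds = ss.spawn(n_sensors)
    slopes, stderrs, r2s = [], [], []
    for s_i, child in zip(true_s, child_seeds):
        spec = SensorSpec(S=float(s_i))
        trace = simulate_capacitance_trace(pressure, spec, noise_sd=noise_sd, seed=child)
        p_kpa, amps = extract_cycle_amplitudes(trace, protocol)
        fit = fit_sensitivity(p_kpa * 1e-3, amps)
        slopes.append(fit.slope)
        stderrs.append(fit.stderr)
        r2s.append(fit.r_squared)
    slopes = np.array(slopes)
    return {
        "true_slopes": true_s,
        "fitted_slopes": slopes,
        "fit_stderrs": np.array(stderrs),
        "r_squared": np.array(r2s),
        "mean_slope": float(slopes.mean()),
        "sem": float(slopes.std(ddof=1) / np.sqrt(n_sensors)),
    }
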