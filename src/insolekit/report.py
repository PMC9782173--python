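"""End-to-end drivers that recompute the headline metrics from scratch.

Each function generates its own synthetic inputs with the package's
simulators, runs the corresponding analysis and returns the measured
quantity; nothing is looked up.  They are shared by the ``report`` CLI
subcommand, the acceptance script and the test suite.
"""

from __future__ import annotations

import numpy as np

from .characterization import (
    FitResult,
    default_hysteresis_loop,
    degree_of_hysteresis,
    durability_drift,
    extract_cycle_amplitudes,
    fit_sensitivity,
    frequency_invariance,
    response_recovery_times,
    sensitivity_study,
)
from .gait_pipeline import calibrate, cop_trajectory, segment_phases, zone_summaries
from .gait_simulator import GaitSpec, default_layout, simulate_gait, to_capacitance
from .rig_simulator import (
    DEFAULT_STAIRCASE_MASSES,
    LoadingProtocol,
    periodic_loading,
    staircase_protocol,
)
from .sensor_model import (
    DEFAULT_P_MAX,
    CapacitanceTrace,
    PressureTrace,
    SensorSpec,
    simulate_capacitance_trace,
)

__all__ = [
    "spec_for_profile",
    "staircase_sensitivity",
    "default_dh",
    "step_response_times",
    "cadence_invariance",
    "durability",
    "gait_roundtrip",
    "full_report",
]


def spec_for_profile(profile: str) -> SensorSpec:
    if profile == "out_of_insole":
        return SensorSpec.out_of_insole()
    if profile == "in_insole":
        return SensorSpec.in_insole()
    raise ValueError(f"unknown sensor profile {profile!r}")


def staircase_sensitivity(
    profile: str = "out_of_insole",
    steps_per_min: float = 40.0,
    duration_per_level: float = 60.0,
    sample_rate: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> FitResult:
    """Full staircase calibration of one simulated sensor.

    Generates the default 15-level staircase, simulates the capacitance
    recording, extracts per-level cycle amplitudes and fits amplitude versus
    pressure (in MPa); the slope is the measured sensitivity.
    """
    spec = spec_for_profile(profile)
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
    trace = simulate_capacitance_trace(pressure, spec, noise_sd=noise_sd, seed=seed)
    p_kpa, amps = extract_cycle_amplitudes(trace, protocol)
    return fit_sensitivity(p_kpa * 1e-3, amps)


def default_dh(profile: str = "out_of_insole", n_points: int = 1000) -> float:
    """Degree of hysteresis of the default quasi-static loop, percent."""
    return degree_of_hysteresis(default_hysteresis_loop(spec_for_profile(profile), n_points))


def step_response_times(
    profile: str = "out_of_insole",
    pressure: float = DEFAULT_P_MAX,
    sample_rate: float = 1000.0,
) -> tuple[float, float]:
    """(10-90% response, 90-10% recovery) in seconds for a full step."""
    spec = spec_for_profile(profile)
    fs = sample_rate
    values = np.concatenate(
        [np.zeros(int(fs)), np.full(int(3 * fs), pressure), np.zeros(int(3 * fs))]
    )
    trace = simulate_capacitance_trace(PressureTrace(fs, values), spec, noise_sd=0.0)
    return response_recovery_times(trace)


def cadence_invariance(
    cadences=(30.0, 40.0, 50.0, 60.0, 70.0),
    pressure: float = DEFAULT_P_MAX,
    n_cycles: int = 20,
    sample_rate: float = 1000.0,
    profile: str = "out_of_insole",
    spec: SensorSpec | None = None,
) -> float:
    """Max relative steady-cycle amplitude deviation across cadences."""
    spec = spec or spec_for_profile(profile)
    traces: dict[float, CapacitanceTrace] = {}
    for cad in cadences:
        p = periodic_loading(pressure, cad, n_cycles=n_cycles, sample_rate=sample_rate)
        traces[cad] = simulate_capacitance_trace(p, spec, noise_sd=0.0)
    return frequency_invariance(traces)


def durability(
    n_cycles: int = 2280,
    steps_per_min: float = 38.0,
    pressure: float = DEFAULT_P_MAX,
    sample_rate: float = 50.0,
    window: float = 60.0,
    profile: str = "out_of_insole",
) -> tuple[float, float]:
    """(C0 drift, Cf drift) of a long noiseless loading run.

    The default 2280 cycles at 38 steps/min reproduce the one-hour
    durability protocol.
    """
    spec = spec_for_profile(profile)
    p = periodic_loading(pressure, steps_per_min, n_cycles=n_cycles, sample_rate=sample_rate)
    trace = simulate_capacitance_trace(p, spec, noise_sd=0.0)
    return durability_drift(trace, window)


def gait_roundtrip(
    n_cycles: int = 3,
    sample_rate: float = 100.0,
    gait_spec: GaitSpec | None = None,
    sensor_noise_sd: float = 0.0,
    seed: int | None = None,
) -> dict:
    """Simulate gait, acquire raw capacitance, calibrate back and analyze.

    Returns the ground-truth frames, the recovered frames, the CoP
    trajectory, the phase segmentation and the zone summary in one dict.
    """
    gait_spec = gait_spec or GaitSpec()
    layout = default_layout()
    truth = simulate_gait(gait_spec, layout, n_cycles=n_cycles, sample_rate=sample_rate)
    specs = [SensorSpec.in_insole() for _ in truth.sensor_ids]
    traces = to_capacitance(truth, specs, noise_sd=sensor_noise_sd, seed=seed)
    recovered = calibrate(traces, specs, order=truth.sensor_ids)
    segmentation = segment_phases(recovered)
    summary = zone_summaries(recovered, segmentation)
    return {
        "truth": truth,
        "recovered": recovered,
        "cop": cop_trajectory(recovered, layout),
        "segmentation": segmentation,
        "summary": summary,
        "layout": layout,
    }


def full_report(
    seed: int = 0,
    duration_per_level: float = 30.0,
    sample_rate: float = 1000.0,
    durability_cycles: int = 2280,
) -> dict:
    """All headline metrics in one JSON-ready document."""
    fit_out = staircase_sensitivity("out_of_insole", duration_per_level=duration_per_level,
                                    sample_rate=sample_rate)
    fit_in = staircase_sensitivity("in_insole", duration_per_level=duration_per_level,
                                   sample_rate=sample_rate)
    study = sensitivity_study(seed=seed)
    t_resp, t_rec = step_response_times()
    c0_drift, cf_drift = durability(n_cycles=durability_cycles)
    gait = gait_roundtrip()
    sensors = gait["summary"]["sensors"]
    truth_labels = gait["truth"].labels
    seg_labels = gait["segmentation"].labels
    match = float(np.mean([a == b for a, b in zip(truth_labels, seg_labels)]))
    return {
        "schema_version": 1,
        "seed": seed,
        "sensitivity": {
            "out_of_insole_slope_mpa": fit_out.slope,
            "out_of_insole_r_squared": fit_out.r_squared,
            "in_insole_slope_mpa": fit_in.slope,
            "in_insole_r_squared": fit_in.r_squared,
            "noisy_batch_mean_slope_mpa": study["mean_slope"],
            "noisy_batch_sem_mpa": study["sem"],
        },
        "hysteresis": {"dh_percent": default_dh()},
        "timing": {"response_ms": t_resp * 1e3, "recovery_ms": t_rec * 1e3},
        "frequency_invariance": cadence_invariance(),
        "durability": {"c0_drift": c0_drift, "cf_drift": cf_drift},
        "gait": {
            "peaks_kpa": {sid: info["peak_kpa"] for sid, info in sensors.items()},
            "arch_below_limit": gait["summary"]["arch_below_limit"],
            "label_match_fraction": match,
        },
    }
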