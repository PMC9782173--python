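import numpy as np
import pytest

from insolekit.characterization import (
    HysteresisLoop,
    degree_of_hysteresis,
    default_hysteresis_loop,
    durability_drift,
    extract_cycle_amplitudes,
    fit_sensitivity,
    frequency_invariance,
    hysteresis_loop_from_trace,
    response_recovery_times,
    sensitivity_study,
)
from insolekit.errors import (
    FitError,
    InsufficientDataError,
    NoEdgeError,
    UndefinedHysteresisError,
)
from insolekit.rig_simulator import (
    DEFAULT_STAIRCASE_MASSES,
    LoadingProtocol,
    periodic_loading,
    ramp_cycle,
    staircase_protocol,
)
from insolekit.sensor_model import (
    CapacitanceTrace,
    SensorSpec,
    simulate_capacitance_trace,
)


def _staircase_trace(spec, duration_per_level=15.0, sample_rate=500.0, noise_sd=0.0, seed=None):
    protocol = LoadingProtocol(
        "staircase", list(DEFAULT_STAIRCASE_MASSES),
        steps_per_min=40.0, duration_per_level=duration_per_level, sample_rate=sample_rate,
    )
    pressure = staircase_protocol(
        protocol.levels, 40.0, duration_per_level, sample_rate=sample_rate
    )
    trace = simulate_capacitance_trace(pressure, spec, noise_sd=noise_sd, seed=seed)
    return trace, protocol


class TestExtractCycleAmplitudes:
    def test_noiseless_top_level_amplitude(self, out_spec):
        trace, protocol = _staircase_trace(out_spec)
        pressures, amps = extract_cycle_amplitudes(trace, protocol)
        assert pressures[-1] == pytest.approx(872.4, abs=0.05)
        assert amps[-1] == pytest.approx(1.038, abs=0.005)

    def test_constant_trace_all_zero(self, out_spec):
        protocol = LoadingProtocol("staircase", [0.7, 1.7], steps_per_min=40.0,
                                   duration_per_level=3.0, sample_rate=100.0)
        trace = CapacitanceTrace(100.0, np.full(600, out_spec.C0))
        _, amps = extract_cycle_amplitudes(trace, protocol)
        np.testing.assert_allclose(amps, 0.0)

    def test_amplitudes_strictly_increasing(self, out_spec):
        trace, protocol = _staircase_trace(out_spec)
        _, amps = extract_cycle_amplitudes(trace, protocol)
        assert np.all(np.diff(amps) > 0)

    def test_too_few_cycles(self, out_spec):
        protocol = LoadingProtocol("staircase", [0.7], steps_per_min=40.0,
                                   duration_per_level=1.5, sample_rate=100.0)
        trace = CapacitanceTrace(100.0, np.full(150, out_spec.C0))
        with pytest.raises(InsufficientDataError):
            extract_cycle_amplitudes(trace, protocol)


class TestFitSensitivity:
    def test_trivial_line(self):
        fit = fit_sensitivity([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_out_of_insole_slope(self, out_spec):
        trace, protocol = _staircase_trace(out_spec)
        pressures, amps = extract_cycle_amplitudes(trace, protocol)
        fit = fit_sensitivity(pressures * 1e-3, amps)
        assert fit.slope == pytest.approx(1.19, abs=0.005)
        assert fit.r_squared > 0.999999

    def test_in_insole_slope(self, in_spec):
        trace, protocol = _staircase_trace(in_spec)
        pressures, amps = extract_cycle_amplitudes(trace, protocol)
        fit = fit_sensitivity(pressures * 1e-3, amps)
        assert fit.slope == pytest.approx(0.55, abs=0.005)

    def test_degenerate_x(self):
        with pytest.raises(FitError):
            fit_sensitivity([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_sensitivity([0.0, 1.0], [0.0, 1.0])


class TestDegreeOfHysteresis:
    def test_default_loop_dh(self):
        assert degree_of_hysteresis(default_hysteresis_loop()) == pytest.approx(9.8, abs=0.05)

    def test_identical_branches_zero(self):
        grid = np.linspace(0, 800, 100)
        loop = HysteresisLoop(grid, grid * 1e-3, grid * 1e-3)
        assert degree_of_hysteresis(loop) == 0.0

    def test_zero_loading_area(self):
        grid = np.linspace(0, 800, 100)
        with pytest.raises(UndefinedHysteresisError):
            degree_of_hysteresis(HysteresisLoop(grid, np.zeros(100), grid * 1e-3))

    def test_closed_form_oracle(self):
        """Numeric DH matches 100*alpha*p_max/(3S) for random loop shapes."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            S = rng.uniform(0.3, 2.0)
            p_max = rng.uniform(200.0, 872.4)
            alpha = rng.uniform(0.0, 0.9 * S / (p_max * 1e-3))
            spec = SensorSpec(S=S, alpha=alpha, p_max=p_max)
            loop = default_hysteresis_loop(spec, n_points=1000)
            expected = 100.0 * alpha * (p_max * 1e-3) / (3.0 * S)
            assert degree_of_hysteresis(loop) == pytest.approx(expected, abs=0.1)

    def test_loop_from_ramp_trace(self, out_spec):
        # slow ramps keep the dynamic lag small; the residual quasi-static
        # approximation error still inflates DH by a few tenths of a point
        protocol = LoadingProtocol("ramp_cycles", [872.4], levels_unit="kPa",
                                   n_cycles=3, sample_rate=50.0, ramp_duration=120.0)
        pressure = ramp_cycle(872.4, 3, 50.0, 120.0)
        trace = simulate_capacitance_trace(pressure, out_spec, noise_sd=0.0)
        loop = hysteresis_loop_from_trace(trace, protocol)
        assert degree_of_hysteresis(loop) == pytest.approx(9.8, abs=1.0)


class TestResponseRecoveryTimes:
    def test_default_step(self, out_spec, step_pressure):
        trace = simulate_capacitance_trace(step_pressure, out_spec, noise_sd=0.0)
        t_resp, t_rec = response_recovery_times(trace)
        assert t_resp == pytest.approx(0.142, abs=0.002)
        assert t_rec == pytest.approx(0.160, abs=0.002)

    def test_instantaneous_step(self):
        x = np.concatenate([np.zeros(50), np.ones(50), np.zeros(50)])
        t_resp, t_rec = response_recovery_times(
            CapacitanceTrace(100.0, 1e-12 * (1 + x), units="F")
        )
        assert t_resp <= 1 / 100.0
        assert t_rec <= 1 / 100.0

    def test_scale_invariance(self, out_spec, step_pressure):
        trace = simulate_capacitance_trace(step_pressure, out_spec, noise_sd=0.0)
        scaled = CapacitanceTrace(trace.sample_rate, trace.values * 1e3, units="F")
        assert response_recovery_times(trace) == pytest.approx(
            response_recovery_times(scaled)
        )

    def test_doubling_taus_doubles_times(self, out_spec, step_pressure):
        slow = out_spec.with_(tau_rise=2 * out_spec.tau_rise,
                              tau_fall=2 * out_spec.tau_fall)
        fast_times = response_recovery_times(
            simulate_capacitance_trace(step_pressure, out_spec, noise_sd=0.0)
        )
        slow_times = response_recovery_times(
            simulate_capacitance_trace(step_pressure, slow, noise_sd=0.0)
        )
        assert slow_times[0] == pytest.approx(2 * fast_times[0], rel=0.02)
        assert slow_times[1] == pytest.approx(2 * fast_times[1], rel=0.02)

    def test_no_edge(self):
        with pytest.raises(NoEdgeError):
            response_recovery_times(CapacitanceTrace(100.0, np.full(100, 1e-12)))


class TestFrequencyInvariance:
    @staticmethod
    def _trace_at(cadence, spec, n_cycles=10, fs=500.0):
        p = periodic_loading(872.4, cadence, n_cycles=n_cycles, sample_rate=fs)
        return simulate_capacitance_trace(p, spec, noise_sd=0.0)

    def test_default_model_invariant(self, out_spec):
        traces = {cad: self._trace_at(cad, out_spec) for cad in (30, 40, 50, 60, 70)}
        assert frequency_invariance(traces) < 0.01

    def test_identical_traces_zero(self, out_spec):
        tr = self._trace_at(40, out_spec)
        assert frequency_invariance({40: tr, 50: tr}) == pytest.approx(0.0, abs=1e-9)

    def test_slow_recovery_detected(self, out_spec):
        sluggish = out_spec.with_(tau_fall=10 * out_spec.tau_fall)
        traces = {cad: self._trace_at(cad, sluggish) for cad in (30, 70)}
        assert frequency_invariance(traces) > 0.05

    def test_single_cadence(self, out_spec):
        with pytest.raises(InsufficientDataError):
            frequency_invariance({40: self._trace_at(40, out_spec)})


class TestDurabilityDrift:
    @staticmethod
    def _run(spec, n_cycles=120, fs=50.0):
        p = periodic_loading(872.4, 40.0, n_cycles=n_cycles, sample_rate=fs)
        return simulate_capacitance_trace(p, spec, noise_sd=0.0)

    def test_noiseless_run_no_drift(self, out_spec):
        trace = self._run(out_spec)
        c0_drift, cf_drift = durability_drift(trace, window=60.0)
        assert abs(c0_drift) < 1e-4
        assert abs(cf_drift) < 1e-4

    def test_injected_baseline_drift_detected(self, out_spec):
        trace = self._run(out_spec)
        drifted = CapacitanceTrace(
            trace.sample_rate,
            trace.values + out_spec.C0 * np.linspace(0.0, 0.05, len(trace)),
        )
        # windows short relative to the trace: their centers span ~94% of
        # the ramp, so the full 5% drift is resolved
        c0_drift, _ = durability_drift(drifted, window=10.0)
        assert c0_drift == pytest.approx(0.05, abs=0.005)

    def test_half_trace_windows_tile(self, out_spec):
        trace = self._run(out_spec, n_cycles=80)
        duration = trace.duration
        c0a, cfa = durability_drift(trace, window=duration / 2)
        assert np.isfinite(c0a) and np.isfinite(cfa)

    def test_short_trace_rejected(self, out_spec):
        trace = self._run(out_spec, n_cycles=20)
        with pytest.raises(InsufficientDataError):
            durability_drift(trace, window=60.0)


class TestSensitivityStudy:
    def test_batch_statistics(self):
        study = sensitivity_study(seed=0)
        assert abs(study["mean_slope"] - 1.19) <= 3 * study["sem"]
        assert 0.015 <= study["sem"] <= 0.045
        assert np.all(study["r_squared"] >= 0.99)

    def test_per_sensor_recovery(self):
        study = sensitivity_study(seed=1)
        # fitted slopes track the per-sensor truth closely (noise floor only)
        np.testing.assert_allclose(
            study["fitted_slopes"], study["true_slopes"], atol=0.02
        )
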