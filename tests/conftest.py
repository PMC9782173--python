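import numpy as np
import pytest

from insolekit.gait_simulator import GaitSpec, default_layout, simulate_gait
from insolekit.sensor_model import PressureTrace, SensorSpec


@pytest.fixture(scope="session")
def out_spec():
    return SensorSpec.out_of_insole()


@pytest.fixture(scope="session")
def in_spec():
    return SensorSpec.in_insole()


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def default_gait():
    """Noiseless default gait simulation: 3 cycles at 100 Hz."""
    return simulate_gait(GaitSpec(), default_layout(), n_cycles=3, sample_rate=100.0)


@pytest.fixture
def step_pressure():
    """0 -> 872.4 -> 0 kPa step at 1 kHz with long plateaus."""
    fs = 1000.0
    values = np.concatenate(
        [np.zeros(int(fs)), np.full(int(3 * fs), 872.4), np.zeros(int(3 * fs))]
    )
    return PressureTrace(fs, values)
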