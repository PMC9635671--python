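import numpy as np
import pytest

from aletrack import CurveNoiseConfig, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small but otherwise default-condition simulation."""
    return SimulationConfig(n_strains=12, replicates_per_strain=3, seed=42)


@pytest.fixture
def noiseless_curve_config():
    return CurveNoiseConfig(spike_probability=0.0, multiplicative_noise_sd=0.0,
                            lag_h=0.0)


def exact_exponential_curve(doubling_time_h, n0=5e4, interval_h=1.0 / 3.0,
                            duration_h=72.0, cap=None):
    """Noiseless exponential growth sampled like the scanner would."""
    times = np.arange(int(duration_h / interval_h) + 1) * interval_h
    cells = n0 * 2.0 ** (times / doubling_time_h)
    if cap is not None:
        cells = np.minimum(cells, cap)
    return times, cells
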