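import numpy as np
import pytest

from gaitmark.io import SignalChannel, TrialRecord
from gaitmark.simulate import SimParams, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_params():
    """Artifact-free, noise-free short trial at the desk rate."""
    return SimParams(duration_s=30.0, rate_hz=100.0, noise_sd_N=0.0,
                     heel_noise_sd_mm=0.0, drag_rate=0.0, cross_plate_rate=0.0,
                     seed=11)


@pytest.fixture(scope="session")
def clean_trial(clean_params):
    return simulate_trial(clean_params)


@pytest.fixture(scope="session")
def noisy_trial():
    params = SimParams(duration_s=30.0, rate_hz=100.0, drag_rate=0.3,
                       cross_plate_rate=0.3, seed=21)
    return simulate_trial(params)


@pytest.fixture
def small_trial():
    """Tiny hand-built trial for I/O round-trips (mixed rates)."""
    g = np.linspace(0.0, 700.0, 40)
    h = np.linspace(0.0, 150.0, 5)
    return TrialRecord(
        trial_id="tiny",
        body_weight_N=712.5,
        grf_left=SignalChannel(g, 1000.0, "grf_vertical"),
        grf_right=SignalChannel(g[::-1].copy(), 1000.0, "grf_vertical"),
        heel_left=SignalChannel(h, 100.0, "heel_height"),
        heel_right=SignalChannel(h[::-1].copy(), 100.0, "heel_height"),
        condition="exo",
    )
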