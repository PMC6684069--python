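import numpy as np
import pytest

from cpgnet.recording import Recording
from cpgnet.synthetic import GroundTruthNetwork, SimulationParams, simulate_recording


@pytest.fixture(scope="session")
def locked_pair():
    """Strongly coupled two-channel burst recording plus its phases."""
    net = GroundTruthNetwork(
        labels=["meso_L", "meso_R"],
        coupling=np.array([[0.0, 1.0], [1.0, 0.0]]),
        intrinsic_freqs=np.array([0.2, 0.2]),
    )
    params = SimulationParams(duration=300.0, seed=11)
    rec, phases = simulate_recording(net, params)
    return net, params, rec, phases


@pytest.fixture(scope="session")
def noise_free_pair():
    """Deterministic burst recording (no phase or observation noise)."""
    net = GroundTruthNetwork(
        labels=["meso_L", "meso_R"],
        coupling=np.array([[0.0, 0.3], [0.3, 0.0]]),
        intrinsic_freqs=np.array([0.2, 0.21]),
    )
    params = SimulationParams(
        duration=200.0, seed=3, phase_noise_sd=0.0, obs_noise_sd=0.0
    )
    rec, phases = simulate_recording(net, params)
    return net, params, rec, phases


@pytest.fixture
def tone_recording():
    """Pure 0.2 Hz cosine at 200 Hz, already zero mean."""
    rate = 200.0
    t = np.arange(0, 60.0, 1 / rate)
    return Recording(
        rate=rate,
        channels={"meso_L": np.cos(2 * np.pi * 0.2 * t)},
        stage="raw",
    ), t
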