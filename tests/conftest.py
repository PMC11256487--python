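import numpy as np
import pytest

from remoteeg.acquisition import get_device_spec
from remoteeg.recording_io import Recording
from remoteeg.session_engine import SessionConfig, TaskSpec
from remoteeg.signal_sim import SimulationPlan, simulate_recording


@pytest.fixture(scope="session")
def small_oddball_config() -> SessionConfig:
    """A short session: two rest blocks and one 40-trial oddball block."""
    return SessionConfig(
        tasks=(
            TaskSpec(kind="rest_eyes_open", duration_s=10.0),
            TaskSpec(kind="rest_eyes_closed", duration_s=10.0),
            TaskSpec(kind="oddball", n_trials=40, p_oddball=0.2, isi_s=0.5),
            TaskSpec(kind="rest_eyes_open", duration_s=5.0),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_recording(small_oddball_config) -> Recording:
    return simulate_recording(SimulationPlan(session_config=small_oddball_config, seed=11))


@pytest.fixture()
def random_recording() -> Recording:
    """A tiny recording with arbitrary (non-simulated) content."""
    rng = np.random.default_rng(99)
    device = get_device_spec("virtual")
    n = 64
    marker = np.zeros(n, dtype=np.int64)
    marker[[3, 17, 40]] = [1, 2, 1]
    return Recording(
        timestamps=np.arange(n) / device.sampling_rate_hz,
        data=rng.standard_normal((4, n)) * 37.5,
        marker=marker,
        device=device,
        metadata={"note": "fixture"},
    )
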