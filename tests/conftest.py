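import numpy as np
import pytest

from runzc.imu_io import CHANNELS, ImuRecording
from runzc.pipeline import run_gait_analysis
from runzc.simulator import SimulationSpec, simulate_bout


def make_recording(fs_hz: float = 60.0, n: int = 600, **channels) -> ImuRecording:
    """Recording with given channels, zeros elsewhere."""
    data = {ch: np.zeros(n) for ch in CHANNELS}
    for ch, values in channels.items():
        arr = np.asarray(values, dtype=float)
        data[ch] = arr
        n = arr.size
    data = {ch: (v if v.size == n else np.zeros(n)) for ch, v in data.items()}
    return ImuRecording(fs_hz=fs_hz, **data)


@pytest.fixture
def noise_free_bout():
    """One noise-free simulated bout (12 km/h, pronated heel-striker) + truth."""
    spec = SimulationSpec(
        speed_kmh=12.0, n_steps=20, pronation_deg=8.0, footstrike="heel",
        noise_acc_g=0.0, seed=7,
    )
    return simulate_bout(spec)


@pytest.fixture
def analyzed_bout(noise_free_bout):
    recording, truth = noise_free_bout
    return run_gait_analysis(recording), truth, recording
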