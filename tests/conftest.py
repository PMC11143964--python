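import numpy as np
import pytest

from cardiomotion import synthgen
from cardiomotion.cellmech import SLSParams, StretchProtocol
from cardiomotion.core import MotionSignal


@pytest.fixture(scope="session")
def analytic_signal() -> MotionSignal:
    """Noise-free 1 Hz beat waveform sampled like a 10 s / 37 fps movie."""
    params = synthgen.BeatWaveformParams(noise_sd=0.0)
    t = np.arange(369) / 37.0 + 1.0 / 74.0
    return MotionSignal(t=t, v=np.abs(synthgen.beat_waveform(params, t)))


@pytest.fixture(scope="session")
def small_video():
    """Short default-noise beating video (kept small for test speed)."""
    params = synthgen.BeatWaveformParams(seed=3)
    seq, truth = synthgen.generate_beating_video(
        params, n_frames=150, image_size=96
    )
    return params, seq, truth


@pytest.fixture(scope="session")
def unit_sls() -> SLSParams:
    """E_parallel = E_series = 1 kPa, tau = 1 s."""
    return SLSParams.from_tau(1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def default_protocol() -> StretchProtocol:
    return StretchProtocol()
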