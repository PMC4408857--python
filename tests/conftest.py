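import numpy as np
import pytest

from eegosc.block import EEGBlock
from eegosc.model import OscillatorParams, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def feasible_params():
    """Feasible mid-range parameters used by recovery-style tests."""
    return OscillatorParams(3000.0, 800.0, 120.0, 60.0, 40.0, 20.0, 1.5)


@pytest.fixture
def short_cfg():
    """Short simulation config for fast tests."""
    return SimulationConfig(duration=5.0, burn_in=1.0, seed=0)


def make_tone(freq_hz: float, fs: float = 125.0, duration: float = 40.0,
              amplitude: float = 1.0, phase: float = 0.0) -> EEGBlock:
    t = np.arange(int(duration * fs)) / fs
    return EEGBlock(amplitude * np.sin(2 * np.pi * freq_hz * t + phase), fs=fs)


@pytest.fixture
def tone_10hz():
    return make_tone(10.0)
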