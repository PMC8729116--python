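import numpy as np
import pytest

from borborygmi.audio_io import AudioRecording


@pytest.fixture
def fs() -> int:
    return 11025


@pytest.fixture
def tone_rec(fs):
    """1 s, 400 Hz unit sine at the default rate."""
    t = np.arange(fs) / fs
    return AudioRecording(np.sin(2 * np.pi * 400 * t), fs)


@pytest.fixture
def noise_rec(fs):
    """2 s of white noise (seeded)."""
    rng = np.random.default_rng(7)
    return AudioRecording(0.3 * rng.standard_normal(2 * fs), fs)
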