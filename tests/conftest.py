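import numpy as np
import pytest

import eegcs


@pytest.fixture(scope="session")
def small_recording() -> eegcs.Recording:
    """2 channels x 8 s at 250 Hz: enough for 8 frames of N=500."""
    config = eegcs.RecordingConfig(n_channels=2, duration_s=8.0, fs=250.0, seed=101)
    return eegcs.generate_recording(config)


@pytest.fixture(scope="session")
def small_frames(small_recording) -> eegcs.FrameSet:
    return eegcs.frame_recording(small_recording, 2.0)


@pytest.fixture(scope="session")
def tiny_frames() -> eegcs.FrameSet:
    """10 frames of N=64 for fast sensing/training tests."""
    config = eegcs.RecordingConfig(n_channels=2, duration_s=1.28, fs=250.0, seed=7)
    recording = eegcs.generate_recording(config)
    return eegcs.frame_recording(recording, 0.256)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
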