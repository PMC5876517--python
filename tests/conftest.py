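import numpy as np
import pytest

from wearecg import (
    EcgConfig,
    design_biquad,
    generate_ecg,
)
from wearecg.filters import BUTTERWORTH_Q

FS = 250.0


@pytest.fixture(scope="session")
def notch60():
    return design_biquad("notch", 60.0, BUTTERWORTH_Q, FS)


@pytest.fixture(scope="session")
def highpass067():
    return design_biquad("highpass", 0.67, BUTTERWORTH_Q, FS)


@pytest.fixture(scope="session")
def lowpass100():
    return design_biquad("lowpass", 100.0, BUTTERWORTH_Q, FS)


@pytest.fixture(scope="session")
def clean60():
    """10 s noise-free 60 BPM ECG with ground-truth R peaks."""
    return generate_ecg(EcgConfig(bpm=60, fs=FS, duration=10.0, seed=0))


@pytest.fixture(scope="session")
def clean60_long():
    """30 s noise-free 60 BPM ECG."""
    return generate_ecg(EcgConfig(bpm=60, fs=FS, duration=30.0, seed=0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
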