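import numpy as np
import pytest

from neurotrust.parcellation import CHANNELS_20
from neurotrust.recording import EEGRecording

FS = 256.0


def make_recording(samples, fs=FS, names=None):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if names is None:
        names = CHANNELS_20[: samples.shape[0]]
    return EEGRecording(samples=samples, fs=fs, channel_names=tuple(names))


def sine(freq, duration_s=4.0, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
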