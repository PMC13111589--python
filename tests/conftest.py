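import numpy as np
import pytest

from eegmark.core_signal import Recording

RATE = 400.0


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_recording(data, rate=RATE, labels=None, montage=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    return Recording(data=data, rate=rate, channel_labels=labels, montage=montage)


def sinusoid(freq, duration=10.0, rate=RATE, amp=1.0, phase=0.0):
    t = np.arange(int(duration * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t + phase)
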