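import numpy as np
import pytest

from mubold.core import EEGRecording
from mubold.paradigm import generate_paradigm


@pytest.fixture(scope="session")
def small_paradigm():
    """One run, each condition once: 4 task blocks + rests, 152 s."""
    return generate_paradigm(n_runs=1, blocks_per_condition=1, seed=11)


@pytest.fixture(scope="session")
def medium_paradigm():
    """One run, 3 blocks per condition (12 trials each), for ERD averaging."""
    return generate_paradigm(n_runs=1, blocks_per_condition=3, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_recording(n_seconds=10.0, fs=250.0, channels=("C3", "C4"),
                   fill=0.0):
    n = int(n_seconds * fs)
    data = np.full((len(channels), n), float(fill))
    return EEGRecording(list(channels), fs, data)


@pytest.fixture()
def sinusoid_recording():
    """10 s of a pure 10 Hz, 10 uV sinusoid on both channels at 250 Hz."""
    fs = 250.0
    t = np.arange(int(10 * fs)) / fs
    sig = 10.0 * np.sin(2 * np.pi * 10.0 * t)
    return EEGRecording(["C3", "C4"], fs, np.vstack([sig, sig]))
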