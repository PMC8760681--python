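import numpy as np
import pytest

from optolfp.io_core import SessionLayout
from optolfp.preprocess import MaskedSignal


@pytest.fixture(scope="session")
def small_layout():
    """10-min 'hours' so whole sessions stay cheap."""
    return SessionLayout(hour_s=600.0, fadeoff_s=100.0)


@pytest.fixture(scope="session")
def tiny_layout():
    return SessionLayout(hour_s=120.0, fadeoff_s=20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_signal(samples, fs=500.0, mask=None):
    return MaskedSignal(np.asarray(samples, dtype=float), fs, mask)


@pytest.fixture()
def white_signal(rng):
    """60 s of white noise at 500 Hz."""
    return make_signal(rng.normal(0, 0.2, 30000))
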