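import numpy as np
import pytest
from hypothesis import settings

from hyperdfc import RegionalTimeSeries

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_series(rng):
    """Single-run white-noise series: 50 regions, 600 samples at TR 2 s."""
    values = rng.standard_normal((600, 50))
    return RegionalTimeSeries(values, 2.0, (600,), ("rest",))


def make_series(values, tr=2.0, task="rest"):
    values = np.asarray(values, dtype=float)
    return RegionalTimeSeries(values, tr, (values.shape[0],), (task,))
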