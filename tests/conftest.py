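import numpy as np
import pytest

from noisenight import synthetic
from noisenight.peaks import PeakConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def schedule60():
    return synthetic.make_schedule("noise60")


@pytest.fixture(scope="session")
def schedule30():
    return synthetic.make_schedule("noise30")


@pytest.fixture(scope="session")
def schedule_control():
    return synthetic.make_schedule("control")


@pytest.fixture(scope="session")
def night60():
    """One default 60-event night, reused by read-only tests."""
    return synthetic.simulate_night(
        synthetic.make_schedule("noise60"), synthetic.TraceParams(seed=7)
    )


@pytest.fixture
def default_peak_config():
    return PeakConfig()
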