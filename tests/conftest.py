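import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from silentwing.synthpop import SynthSpec, make_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic architecture: two opposite-phase populations of
    90 males, inversion 7.5-80 Mb at q=0.4, d=0.3, penetrance 0.9."""
    return make_dataset(SynthSpec(), np.random.default_rng(2024))


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast dataset for I/O and plumbing tests."""
    spec = SynthSpec(n_per_pop=25, n_snps=150, missing_rate=0.05)
    return make_dataset(spec, np.random.default_rng(7))
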