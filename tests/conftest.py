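import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_standardized(rng):
    """A standardized 30 x 8 matrix with mild low-rank structure."""
    from spcakit import center_scale

    base = rng.standard_normal((30, 3)) @ rng.standard_normal((3, 8))
    return center_scale(base + 0.3 * rng.standard_normal((30, 8)))
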