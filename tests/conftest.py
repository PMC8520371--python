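import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def naive_autocorr(x, max_lag):
    """Time-domain biased autocorrelation oracle: explicit per-lag sums."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    return np.array([np.dot(x[: n - m], x[m:]) / n for m in range(max_lag + 1)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
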