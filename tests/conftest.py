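import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# MixedLM emits convergence chatter on small problems; keep test output clean
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def mc_circular_ranges(rng, n, reps):
    """Monte-Carlo null sample of circular ranges for n uniform angles."""
    a = rng.uniform(0.0, 360.0, size=(reps, n))
    a.sort(axis=1)
    gaps = np.diff(a, axis=1)
    wrap = a[:, 0] + 360.0 - a[:, -1]
    return 360.0 - np.maximum(gaps.max(axis=1), wrap)
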