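import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import planotaxis as pt

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def geom40():
    return pt.EyeGeometry(binocular_field=40.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_band(bf: float, tau: float, step: float = 0.01):
    """Independent grid-scan oracle for the response band.

    Scans |R - L| on a dense positive-bearing grid and returns the first
    and last bearing exceeding the threshold, or None when none does.
    """
    geom = pt.EyeGeometry(binocular_field=bf)
    theta = np.arange(0.0, 180.0 + step, step)
    diff = np.abs(pt.input_difference(theta, geom))
    above = np.nonzero(diff > tau)[0]
    if above.size == 0:
        return None
    return theta[above[0]], theta[above[-1]]
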