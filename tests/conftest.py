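import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import strindex as sx

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def locus():
    return sx.HTT_CAG_LOCUS


@pytest.fixture
def worked_peaks(locus):
    """Five-peak sample whose indices are known in closed form:
    all = 80/190, expansion = 100/190, contraction = -20/190 at threshold 5%."""
    return sx.RepeatPeakSet(
        "worked", {108: 5.0, 109: 10.0, 110: 100.0, 111: 50.0, 112: 25.0}, locus
    )


def random_peak_set(rng, locus, max_peaks=12):
    """Random peak set inside the locus window with lognormal heights."""
    n = int(rng.integers(1, max_peaks + 1))
    repeats = rng.choice(
        np.arange(locus.window_min_repeat, locus.window_max_repeat + 1),
        size=n, replace=False,
    )
    heights = np.exp(rng.normal(4.0, 2.0, size=n))
    return sx.RepeatPeakSet(
        "rand", {int(r): float(h) for r, h in zip(repeats, heights)}, locus
    )
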