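import numpy as np
import pytest

from postmeal.trace import GlucoseTrace

GRID = np.arange(0.0, 301.0, 15.0)


def make_trace(values, times=None, subject_id="S01", arm=""):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = GRID[: values.size]
    return GlucoseTrace(times=np.asarray(times, dtype=float), values=values,
                        subject_id=subject_id, arm=arm)


@pytest.fixture
def constant_trace():
    return make_trace(np.full(21, 7.0))


@pytest.fixture
def ramp_trace():
    """Linear 6 → 10 mmol/L over 0–300 min on the 15-min grid."""
    return make_trace(6.0 + 4.0 * GRID / 300.0)


def random_trace(rng, n_min=5, n_max=21, subject_id="S01", arm=""):
    """Random strictly-positive trace on the 15-min grid."""
    n = int(rng.integers(n_min, n_max + 1))
    values = rng.uniform(2.5, 14.0, size=n)
    return make_trace(values, times=GRID[:n], subject_id=subject_id, arm=arm)
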