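import numpy as np
import pytest

import mrpe


@pytest.fixture
def hill_series():
    """(1,2,3,2,1): two ascending and two descending m=2 windows."""
    return mrpe.RRSeries(np.array([1.0, 2.0, 3.0, 2.0, 1.0]), subject="hill")


@pytest.fixture
def sawtooth_series():
    """Alternating 1,2,1,2,...: every m=2 window has variance 0.25."""
    return mrpe.RRSeries(np.array([1.0, 2.0] * 40), subject="sawtooth")


@pytest.fixture(scope="session")
def synthetic_cohorts():
    """Three pinned-seed cohorts (3 subjects each) emulating AF / H / CHF."""
    T = 20_000
    return {
        "AF": mrpe.synth_group("iid_like", 3, T, seed=1, group="AF"),
        "H": mrpe.synth_group("correlated", 3, T, seed=1, group="H"),
        "CHF": mrpe.synth_group("low_variability", 3, T, seed=1, group="CHF"),
    }


def naive_pattern_counts(x, m, tau):
    """Independent double-loop oracle: re-sorts every window from scratch."""
    x = list(x)
    n = len(x) - (m - 1) * tau
    counts = {}
    for j in range(n):
        window = [x[j + i * tau] for i in range(m)]
        # positions sorted by (value, position): the stable Bandt-Pompe rule
        order = tuple(sorted(range(1, m + 1), key=lambda pos: (window[pos - 1], pos)))
        counts[order] = counts.get(order, 0) + 1
    return {k: v / n for k, v in counts.items()}
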