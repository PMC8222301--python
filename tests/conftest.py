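import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20091112)


def brute_force_connectivity(offsets, delta):
    """O(n^2) reference pair counter: per-event counts of later events
    (sort order) within delta seconds, and their mean."""
    off = list(offsets)
    n = len(off)
    per = []
    for i in range(n):
        c = 0
        for j in range(i + 1, n):
            if off[j] - off[i] <= delta:
                c += 1
        per.append(c)
    return per, sum(per) / n
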