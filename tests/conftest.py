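import numpy as np
import pytest

from fsomtype.io import ASEvent
from fsomtype.synthetic import default_shapes, make_profiles


@pytest.fixture
def plus_event():
    return ASEvent(event_id="ev1", event_type="SE", chrom="chr1", strand="+",
                   body_start=1000, body_end=1200, upstream_limit=800,
                   downstream_limit=1400, psi=0.5)


@pytest.fixture
def four_family_mixture():
    """200 profiles from 4 shape families with noise and length jitter."""
    shapes = default_shapes(noise_sd=0.1, length_jitter=2)
    profiles, labels = make_profiles(shapes, 50, seed=42)
    return profiles, labels


def enumerate_warping_paths(n, m):
    """All monotone, continuous, bounded paths from (0,0) to (n-1,m-1)."""
    stack = [[(0, 0)]]
    while stack:
        path = stack.pop()
        i, j = path[-1]
        if i == n - 1 and j == m - 1:
            yield path
            continue
        if i + 1 < n:
            stack.append(path + [(i + 1, j)])
        if j + 1 < m:
            stack.append(path + [(i, j + 1)])
        if i + 1 < n and j + 1 < m:
            stack.append(path + [(i + 1, j + 1)])


def brute_force_dtw(x, y):
    """Exhaustive minimum of the summed node weights over *all* warping
    paths — an oracle fully independent of the dynamic program.  Only
    usable for tiny sequences."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return min(sum((x[i] - y[j]) ** 2 for i, j in path)
               for path in enumerate_warping_paths(len(x), len(y)))
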