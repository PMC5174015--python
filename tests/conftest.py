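import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # for the oracles module

from myovis import build_weighted_adjacency
from oracles import random_epoch


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture(scope="session")
def random_graphs():
    """100+ random visibility graphs with N <= 12 (connected by construction)."""
    rng = np.random.default_rng(9)
    out = []
    for _ in range(110):
        n = int(rng.integers(4, 13))
        out.append(build_weighted_adjacency(random_epoch(rng, n)))
    return out


# the worked reference network: printed per-node direct-distance matrix of a
# nine-node epoch (zeros mark non-linked pairs)
REFERENCE_DISTANCES = np.array([
    [0.00, 0.72, 0.66, 0.96, 1.00, 0.00, 0.00, 0.00, 0.00],
    [0.72, 0.00, 0.88, 0.74, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.66, 0.88, 0.00, 0.68, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.96, 0.74, 0.68, 0.00, 0.96, 0.00, 0.00, 0.00, 0.00],
    [1.00, 0.00, 0.00, 0.96, 0.00, 0.72, 0.66, 0.96, 1.00],
    [0.00, 0.00, 0.00, 0.00, 0.72, 0.00, 0.88, 0.74, 0.00],
    [0.00, 0.00, 0.00, 0.00, 0.66, 0.88, 0.00, 0.68, 0.00],
    [0.00, 0.00, 0.00, 0.00, 0.96, 0.74, 0.68, 0.00, 0.96],
    [0.00, 0.00, 0.00, 0.00, 1.00, 0.00, 0.00, 0.96, 0.00],
])

#: printed per-node clustering coefficients of the reference network
REFERENCE_C_I = [0.82, 1.29, 1.32, 0.82, 0.39, 1.29, 1.32, 0.82, 1.02]


@pytest.fixture
def reference_distances():
    return REFERENCE_DISTANCES.copy()
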