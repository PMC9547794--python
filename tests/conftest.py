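import numpy as np
import pytest

from pbesim.discretization import (
    AggregationKernel,
    build_geometric_grid,
    build_pair_index_set,
)
from pbesim.fvs import ParticleState


@pytest.fixture
def grid4():
    """p=1 grid with reps (1, 2, 4, 8), edges (0, 1.5, 3, 6, 12)."""
    return build_geometric_grid(1, 4, 1.0)


@pytest.fixture
def pairs4(grid4):
    return build_pair_index_set(grid4)


@pytest.fixture
def constant_kernel():
    return AggregationKernel("constant", 1.0)


@pytest.fixture
def monodisperse4(grid4):
    N = np.zeros(4)
    m = np.zeros(4)
    N[0] = 1.0
    m[0] = 1.0
    return ParticleState(N=N, m=m)


def random_state(rng, I, scale=1.0):
    return ParticleState(N=scale * rng.random(I), m=scale * rng.random(I))
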