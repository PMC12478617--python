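import numpy as np
import pytest

from acarp.data import ItemResponseMatrix
from acarp.simulate import SimulationDesign, simulate_design


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def bernoulli_matrix(rng):
    """60 x 5 matrix of independent fair-coin items (null model)."""
    return ItemResponseMatrix((rng.random((60, 5)) < 0.5).astype(int))


@pytest.fixture
def dim0_matrix():
    """Larger zero-dimensional response matrix for statistic-level checks."""
    return simulate_design(SimulationDesign(J=5, N=1000, scenario="dim0", seed=5))
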