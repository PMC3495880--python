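import numpy as np
import pytest

from macrodiv.simulate import simulate_yule
from macrodiv.tree import read_newick


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_balanced():
    return read_newick("((A:1,B:1):1.5,(C:2,D:2):0.5);")


@pytest.fixture
def caterpillar():
    return read_newick("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture(scope="session")
def yule_trees():
    """A shared batch of moderate pure-birth trees for property tests."""
    return [simulate_yule(30, 0.5, seed=100 + i) for i in range(8)]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
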