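import numpy as np
import pytest

from dolloloss.dollo_core import read_newick
from dolloloss.toga_io import PresenceMatrix


@pytest.fixture
def quartet():
    return read_newick("((A,B),(C,D));")


@pytest.fixture
def seven_leaf():
    return read_newick("((A,B),((C,D),(E,(F,G))));")


@pytest.fixture
def rng():
    return np.random.default_rng(20240404)


def random_matrix(rng, species, n_genes, p_zero=0.5):
    states = (rng.random((len(species), n_genes)) >= p_zero).astype(np.int8)
    return PresenceMatrix(list(species), [f"g{j}" for j in range(n_genes)], states)
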