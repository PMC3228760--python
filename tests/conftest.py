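import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from scortho.simulate import simulate_species_tree
from scortho.tree_io import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def species_abc():
    """((A,B),C) with leaf labels as taxa."""
    return parse_newick("((A,B),C);")


@pytest.fixture
def species_abcd():
    return parse_newick("(((A,B),C),D);")


@pytest.fixture
def species_factory():
    def make(n_taxa, seed=0):
        return simulate_species_tree(n_taxa, seed=seed)
    return make
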