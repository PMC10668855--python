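import numpy as np
import pytest

from amphievo.core.tree import Tree
from amphievo.synthetic_data import SimConfig, simulate_codon_alignment


@pytest.fixture
def five_taxon_tree():
    return Tree.from_newick("((A:0.2,B:0.3):0.1,(C:0.15,D:0.25):0.1,E:0.2);")


@pytest.fixture
def four_taxon_rooted():
    return Tree.from_newick("((A:0.3,B:0.3):0.15,(C:0.3,D:0.3):0.15);")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_codon_alignment(five_taxon_tree):
    cfg = SimConfig(seed=11, n_sites=200, kappa=2.0, omega=0.3)
    return simulate_codon_alignment(five_taxon_tree, cfg)
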