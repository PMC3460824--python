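import numpy as np
import pandas as pd
import pytest

from phylothreat import Phylogeny, SyntheticConfig, generate_dataset
from phylothreat.synthetic_data import simulate_tree


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2); — PD 5, d(A,B)=2, d(A,C)=d(B,C)=4."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def cherry_with_outgroup() -> Phylogeny:
    """((A:1,B:1):2,C:4); — ED_A = 1 + 2/2 = 2."""
    return Phylogeny.from_newick("((A:1,B:1):2,C:4);")


@pytest.fixture
def random_tree_factory():
    """Ultrametric pure-birth trees of a given size, deterministic per seed."""

    def make(n: int, seed: int, imbalance: float = 0.3) -> Phylogeny:
        return simulate_tree(SyntheticConfig(n_species=n, seed=seed, imbalance=imbalance))

    return make


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-species synthetic bundle with moderate couplings."""
    return generate_dataset(SyntheticConfig(n_species=40, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
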