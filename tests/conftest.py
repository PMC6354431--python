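import numpy as np
import pytest

from osteophylo.synth import simulate_discrete_history, simulate_tree
from osteophylo.trees import Phylogeny


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tree28():
    """A 28-tip unit-height pure-birth tree (the empirical study's size)."""
    return simulate_tree(28, seed=5)


@pytest.fixture(scope="session")
def tree8_with_history():
    tree = simulate_tree(8, seed=11)
    tips, rm = simulate_discrete_history(tree, 1.0, seed=12)
    return tree, tips, rm


@pytest.fixture
def three_taxon_tree():
    """((A:1,B:1):1,C:2) — the hand-checkable covariance fixture."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star8():
    """Star tree: 8 tips on unit branches straight from the root."""
    return Phylogeny(
        np.array([-1] + [0] * 8), np.array([0.0] + [1.0] * 8),
        ["root"] + [f"t{i}" for i in range(1, 9)],
    )
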