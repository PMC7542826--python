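import dendropy
import numpy as np
import pytest


def tree_from_newick(nwk: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=nwk, schema="newick", rooting="force-rooted")


@pytest.fixture
def four_tip_tree():
    return tree_from_newick("((A:0.3,B:0.7):0.4,(C:0.5,D:0.2):0.6);")


@pytest.fixture
def three_tip_tree():
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(20250919)
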