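import io as _io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from gutdiv.io import CountMatrix
from gutdiv.phylo import BranchMatrix
from gutdiv.simulate import SimulationConfig, simulate_experiment, simulate_tree


def tree_from_newick(newick: str) -> TreeNode:
    tree = TreeNode.read(_io.StringIO(newick))
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return tree


@pytest.fixture
def three_leaf_tree():
    return tree_from_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def bm3(three_leaf_tree):
    return BranchMatrix(three_leaf_tree, ["A", "B", "C"])


@pytest.fixture
def small_counts():
    df = pd.DataFrame(
        {"A": [3, 1, 0], "B": [0, 5, 2], "C": [7, 0, 4]},
        index=["o1", "o2", "o3"], dtype=np.int64)
    return CountMatrix(df)


@pytest.fixture(scope="session")
def default_experiment():
    """One full synthetic experiment at the default study design."""
    return simulate_experiment(SimulationConfig(seed=11))


def random_count_vector(rng, n, max_count=50, ensure_positive=True):
    v = rng.integers(0, max_count + 1, size=n)
    if ensure_positive and v.sum() == 0:
        v[rng.integers(n)] = 1
    return v
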