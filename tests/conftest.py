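"""Shared fixtures: small simulated benchmarks and random-tree generators."""

import numpy as np
import pytest

from celltree.simulate import SimConfig, simulate_hierarchical_counts
from celltree.tree import ROOT_NAME, ClassificationTree, TreeNode


@pytest.fixture(scope="session")
def small_sim():
    """Six well-separated populations under the default three-level tree."""
    return simulate_hierarchical_counts(
        SimConfig(n_genes=300, cells_per_leaf=80, seed=0)
    )


@pytest.fixture(scope="session")
def blob_pair():
    """Two well-separated Gaussian clouds in five dimensions."""
    rng = np.random.default_rng(0)
    pos = rng.normal(0.0, 1.0, size=(120, 5))
    neg = rng.normal(6.0, 1.0, size=(120, 5))
    return pos, neg


def random_tree(rng: np.random.Generator, n_nodes: int):
    """Random tree as (ClassificationTree, parent-name map).

    The parent map is returned alongside so oracle code can walk ancestry
    independently of the ClassificationTree implementation.
    """
    names = [f"n{i}" for i in range(n_nodes)]
    nodes = {name: TreeNode(name) for name in names}
    root = TreeNode(ROOT_NAME)
    pool = [root]
    parent_map = {}
    for name in names:
        parent = pool[rng.integers(len(pool))]
        parent.add_child(nodes[name])
        parent_map[name] = parent.name
        pool.append(nodes[name])
    return ClassificationTree(root), parent_map
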