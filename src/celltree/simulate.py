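"""Hierarchically structured synthetic scRNA-seq data.

The generator produces count data whose populations follow a known
classification tree: every branch of the tree carries a sparse set of
differentially expressed (DE) genes with multiplicative log-normal effects,
and a leaf's expression profile is the shared baseline times the product of
the DE factors along its root-to-leaf path.  Sibling leaves therefore share
the DE genes of their common ancestors and are more similar to each other
than to cousins.  Counts are drawn from a gamma-Poisson (negative-binomial)
model with log-normally distributed per-cell library sizes, and the returned
matrix is log2(count + 1).

The default configuration emulates the benchmark used throughout the
package's tests: six well-separated leaf populations of 1500 cells each under
a three-level hierarchy (Group456 -> Group56 -> leaves), 2000 genes.  Batches
at different annotation resolutions are derived by merging subtrees into
their ancestor's label or removing leaf populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tree import ClassificationTree

#: Three-level ground-truth hierarchy of the default benchmark.
DEFAULT_TREE = (
    "(Group1,Group2,Group3,(Group4,(Group5,Group6)Group56)Group456)root;"
)

#: Batch derivation at three annotation resolutions (coarse to fine).
DEFAULT_BATCHES = (
    {"merge": ("Group456",)},
    {"merge": ("Group56",)},
    {},
)


@dataclass
class SimConfig:
    """Parameters of the hierarchical negative-binomial simulator.

    Attributes
    ----------
    tree : str
        Newick text of the ground-truth hierarchy (named internal nodes).
    n_genes : int
    cells_per_leaf : int
    de_prob : float
        Per-branch probability that a gene is differentially expressed.
    de_loc, de_scale : float
        Log-normal location/scale of the multiplicative DE factors; the
        factor direction (up/down) is symmetric.  ``de_loc = 0`` with
        ``de_scale = 0`` makes all populations exchangeable.
    library_loc, library_scale : float
        Log-normal parameters (natural log) of per-cell library sizes.
    dispersion : float
        Negative-binomial dispersion phi (variance = mu + phi * mu^2).
    seed : int
    """

    tree: str = DEFAULT_TREE
    n_genes: int = 2000
    cells_per_leaf: int = 1500
    de_prob: float = 0.1
    de_loc: float = 1.0
    de_scale: float = 0.4
    library_loc: float = float(np.log(20000.0))
    library_scale: float = 0.2
    dispersion: float = 0.1
    seed: int = 0

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class LabeledDataset:
    """Cell-by-gene log-expression matrix with per-cell population labels."""

    X: np.ndarray
    labels: np.ndarray
    cell_ids: np.ndarray = field(default=None)
    gene_names: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object).astype(str)
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("matrix row count must equal label count")
        if self.cell_ids is None:
            self.cell_ids = np.array(
                [f"cell{i}" for i in range(self.X.shape[0])], dtype=object
            )
        if self.gene_names is None:
            self.gene_names = np.array(
                [f"gene{j}" for j in range(self.X.shape[1])], dtype=object
            )

    @property
    def populations(self) -> dict[str, int]:
        """Population name -> number of cells."""
        return pd.Series(self.labels).value_counts().sort_index().to_dict()

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            self.X[idx], self.labels[idx], self.cell_ids[idx], self.gene_names
        )


def simulate_hierarchical_counts(
    config: SimConfig | None = None, **overrides
) -> tuple[LabeledDataset, ClassificationTree]:
    """Simulate a dataset and its ground-truth classification tree.

    Identical configurations (including the seed) give bitwise-identical
    output.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    tree = ClassificationTree.from_newick(config.tree)
    rng = np.random.default_rng(config.seed)

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)

    # one multiplicative factor vector per branch (edge above each non-root
    # node), drawn in preorder so the draw order is deterministic
    log_factors: dict[str, np.ndarray] = {}
    for name in tree.nonroot_names():
        de = rng.random(config.n_genes) < config.de_prob
        magnitude = rng.normal(config.de_loc, config.de_scale, size=config.n_genes)
        sign = rng.choice([-1.0, 1.0], size=config.n_genes)
        log_factors[name] = np.where(de, sign * magnitude, 0.0)

    leaf_names = tree.leaf_names()
    profiles = {}
    for leaf in leaf_names:
        path = [leaf, *tree.ancestors(leaf)]
        lf = np.sum([log_factors[n] for n in path], axis=0)
        mean = baseline * np.exp(lf)
        profiles[leaf] = mean / mean.sum()

    n_cells = config.cells_per_leaf * len(leaf_names)
    X = np.empty((n_cells, config.n_genes))
    labels = np.empty(n_cells, dtype=object)
    row = 0
    for leaf in leaf_names:
        libs = rng.lognormal(
            mean=config.library_loc,
            sigma=config.library_scale,
            size=config.cells_per_leaf,
        )
        mu = libs[:, None] * profiles[leaf][None, :]
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, mu / shape)
        else:
            lam = mu
        counts = rng.poisson(lam)
        X[row : row + config.cells_per_leaf] = np.log2(counts + 1.0)
        labels[row : row + config.cells_per_leaf] = leaf
        row += config.cells_per_leaf

    return LabeledDataset(X, labels), tree


def derive_batches(
    ds: LabeledDataset,
    tree: ClassificationTree,
    scheme=DEFAULT_BATCHES,
    seed: int = 0,
) -> list[LabeledDataset]:
    """Partition a dataset into batches at different annotation resolutions.

    ``scheme`` is a sequence of per-batch maps with optional keys:

    ``merge``
        Internal node names; every cell labelled within such a subtree is
        relabelled with the subtree root's name.
    ``remove``
        Leaf names whose cells are dropped from the batch.

    Cells are shuffled once and partitioned disjointly across the batches.
    """
    rng = np.random.default_rng(seed)
    n = ds.X.shape[0]
    order = rng.permutation(n)
    parts = np.array_split(order, len(scheme))
    batches = []
    for spec, idx in zip(scheme, parts):
        batch = ds.subset(np.sort(idx))
        labels = batch.labels.copy()
        for target in spec.get("merge", ()):
            node = tree.node(target)
            if node.is_leaf:
                raise ValueError(f"merge target {target!r} is not an internal node")
            members = sorted(tree.subtree_labels(target))
            labels = np.where(np.isin(labels, members), target, labels)
        keep = np.ones(len(labels), dtype=bool)
        for target in spec.get("remove", ()):
            tree.node(target)  # must exist
            keep &= ~np.isin(batch.labels, sorted(tree.subtree_labels(target)))
        batches.append(
            LabeledDataset(
                batch.X[keep], labels[keep], batch.cell_ids[keep], batch.gene_names
            )
        )
    return batches
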