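"""Hierarchical cell-identity classifier.

Training walks every non-root node of a classification tree and fits a local
classifier per node (linear max-margin or one-class boundary) on the node's
informative principal components, with positives pooled over the node's
subtree and negatives chosen by the siblings policy.  A reconstruction-error
rejection threshold is calibrated on the same training data.

Prediction is top-down.  A cell whose reconstruction error exceeds the
calibrated threshold is rejected outright.  Otherwise the walk starts at the
root and at each step scores the children of the current node:

1. all children negative — rejected if the current node is the root,
   otherwise the cell is labelled with the current (internal) node's name;
2. one child positive — descend into it (emit its name if it is a leaf);
3. several children positive — descend into the highest-scoring child.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from . import local
from .rejection import PCAReconstructionRejector
from .tree import REJECTED, ClassificationTree, TreeNode


class HierarchicalClassifier(ClassifierMixin, BaseEstimator):
    """Tree-structured classifier with per-node local decision units.

    Parameters
    ----------
    tree : ClassificationTree, Newick str, or None
        Hierarchy to train on.  ``None`` builds a flat tree (depth one) over
        the unique training labels, which is how a freshly annotated dataset
        enters progressive learning.
    kind : {"linear", "one_class"}
        Local classifier family.  The linear max-margin classifier is the
        more accurate of the two; the one-class boundary rejects cells from
        unseen populations better.
    n_components : int, default=100
        Shared PCA dimensionality (capped at the data rank).
    alpha : float, default=0.05
        Family-wise significance level of the per-node informative-component
        t-tests (Bonferroni-corrected by the realised component count).
    q : float, default=0.99
        Percentile for the reconstruction-error rejection threshold.
    nu : float, default=0.05
        Upper bound on the training outlier fraction of the one-class model.
    one_class_kernel : str, default="rbf"
        Kernel of the one-class boundary estimator.
    reject_reconstruction : bool, default=True
        Apply the reconstruction-error filter before the classifier walk.
    random_state : int, default=0
        Seeds PCA and the linear solver; fitting is deterministic given data
        and seed.

    Attributes
    ----------
    tree_ : ClassificationTree
    node_models_ : dict[str, local.NodeClassifier]
        One fitted model per non-root node (the root carries none).
    rejector_ : PCAReconstructionRejector
    pca_ : sklearn PCA shared by all node models (the rejector's projection).
    classes_ : ndarray of possible output labels (tree nodes + "rejected").
    """

    def __init__(
        self,
        tree=None,
        kind="linear",
        n_components=100,
        alpha=0.05,
        q=0.99,
        nu=0.05,
        one_class_kernel="rbf",
        reject_reconstruction=True,
        random_state=0,
    ):
        self.tree = tree
        self.kind = kind
        self.n_components = n_components
        self.alpha = alpha
        self.q = q
        self.nu = nu
        self.one_class_kernel = one_class_kernel
        self.reject_reconstruction = reject_reconstruction
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _resolve_tree(self, y: np.ndarray) -> ClassificationTree:
        if self.tree is None:
            return ClassificationTree.flat(np.unique(y))
        if isinstance(self.tree, str):
            return ClassificationTree.from_newick(self.tree)
        if isinstance(self.tree, ClassificationTree):
            return self.tree.copy()
        raise TypeError(f"unsupported tree specification: {type(self.tree)!r}")

    def fit(self, X, y):
        if self.kind not in ("linear", "one_class"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        X = validate_data(self, X)
        y = np.asarray(y, dtype=object).astype(str)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have different numbers of cells")
        if np.any(y == REJECTED):
            raise ValueError(f'"{REJECTED}" is a reserved label')

        tree = self._resolve_tree(y)
        known = set(tree.nonroot_names())
        offenders = sorted(set(y) - known)
        if offenders:
            raise ValueError(f"labels not present in the tree: {offenders}")
        values, counts = np.unique(y, return_counts=True)
        tiny = [str(v) for v, c in zip(values, counts) if c < 2]
        if tiny:
            raise ValueError(
                f"populations with fewer than 2 training cells: {tiny}"
            )

        self.rejector_ = PCAReconstructionRejector(
            n_components=self.n_components,
            q=self.q,
            random_state=self.random_state,
        ).fit(X)
        self.pca_ = self.rejector_.pca_
        scores = self.pca_.transform(X)

        node_models: dict[str, local.NodeClassifier] = {}
        for name in tree.nonroot_names():
            pos, neg = local.select_training_sets(tree, name, y)
            if pos.size < 2:
                raise ValueError(
                    f"population {name!r} has fewer than 2 training cells"
                )
            sel = local.select_informative_pcs(
                scores[pos], scores[neg], alpha=self.alpha
            )
            node_models[name] = local.fit_node_classifier(
                self.kind,
                scores[np.ix_(pos, sel.selected)],
                scores[np.ix_(neg, sel.selected)] if self.kind == "linear" else None,
                node_name=name,
                nu=self.nu,
                one_class_kernel=self.one_class_kernel,
                random_state=self.random_state,
                selection=sel,
                pc_indices=sel.selected,
            )

        self.tree_ = tree
        self.node_models_ = node_models
        self.classes_ = np.asarray(sorted(known) + [REJECTED], dtype=object)
        return self

    # ------------------------------------------------------------------ #

    def _walk(self, scores: np.ndarray, accepted: np.ndarray):
        """Top-down label walk; returns labels and the last decision score."""
        n = scores.shape[0]
        labels = np.full(n, REJECTED, dtype=object)
        final_score = np.full(n, np.nan)

        calls: dict[str, np.ndarray] = {}
        svals: dict[str, np.ndarray] = {}
        for name, model in self.node_models_.items():
            c, s = model.score_and_classify(scores)
            calls[name], svals[name] = c, s

        def descend(node: TreeNode, idx: np.ndarray) -> None:
            if idx.size == 0:
                return
            if not node.children:
                labels[idx] = node.name
                return
            child_names = [c.name for c in node.children]
            call_mat = np.stack([calls[c][idx] for c in child_names])
            score_mat = np.stack([svals[c][idx] for c in child_names])
            any_pos = call_mat.any(axis=0)
            stay = idx[~any_pos]
            if node is self.tree_.root:
                labels[stay] = REJECTED
            else:
                labels[stay] = node.name
            if not any_pos.any():
                return
            # among positive children take the highest score; exact ties fall
            # to the first child in insertion order (argmax is first-max)
            masked = np.where(call_mat, score_mat, -np.inf)
            best = masked.argmax(axis=0)
            for k, child in enumerate(node.children):
                sub = idx[any_pos & (best == k)]
                final_score[sub] = score_mat[k, any_pos & (best == k)]
                descend(child, sub)

        descend(self.tree_.root, np.flatnonzero(accepted))
        return labels, final_score

    def predict(self, X) -> np.ndarray:
        """Label per cell: a leaf, an internal node, or ``"rejected"``."""
        return self.predict_detail(X)["label"].to_numpy()

    def predict_detail(self, X) -> pd.DataFrame:
        """Labels plus the final decision score and reconstruction error."""
        check_is_fitted(self, "tree_")
        X = validate_data(self, X, reset=False)
        err = self.rejector_.reconstruction_error(X)
        if self.reject_reconstruction:
            accepted = err <= self.rejector_.threshold_
        else:
            accepted = np.ones(len(X), dtype=bool)
        scores = self.pca_.transform(X)
        labels, final_score = self._walk(scores, accepted)
        return pd.DataFrame(
            {
                "label": labels,
                "score": final_score,
                "reconstruction_error": err,
            }
        )

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.classifier_tags.multi_class = True
        return tags


# ---------------------------------------------------------------------- #
# thin functional wrappers
# ---------------------------------------------------------------------- #


def train_hierarchy(
    data, labels, tree=None, kind: str = "linear", **kwargs
) -> HierarchicalClassifier:
    """Train a full hierarchical classifier on a labelled dataset and tree."""
    return HierarchicalClassifier(tree=tree, kind=kind, **kwargs).fit(data, labels)


def predict_labels(h: HierarchicalClassifier, cells) -> np.ndarray:
    """Predict leaf/internal/rejected labels for new cells."""
    return h.predict(cells)
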