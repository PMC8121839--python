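"""Per-node decision units.

Each non-root node of a classification tree gets a local classifier.  Its
positive training cells are the cells labelled with the node or any of its
descendants; its negatives follow the *siblings policy*: cells labelled under
any sibling subtree (siblings share the node's parent, the parent itself is
excluded), falling back to cells labelled exactly as the parent when the node
has no siblings.

To avoid overfitting, classifiers operate on a shared principal-component
decomposition of the training data (100 components by default) and each node
keeps only the components that are informative for its own positives-versus-
negatives contrast, judged by a per-component two-sided Welch t-test at a
Bonferroni-corrected level alpha / n_components.  When no component survives
the correction, the five smallest-p components are kept instead.

Two classifier kinds are supported:

``linear``
    L2-regularised linear max-margin classifier on positives vs negatives
    (scikit-learn ``LinearSVC``).
``one_class``
    One-class boundary estimator fitted on positives only with outlier
    fraction ``nu`` (scikit-learn ``OneClassSVM``), giving a tight decision
    boundary usable for novelty rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC, OneClassSVM

from .tree import ClassificationTree


@dataclass
class PCSelection:
    """Informative-component selection for one node."""

    alpha: float
    n_components: int
    p_values: np.ndarray
    selected: np.ndarray  # sorted ascending component indices (0-based)
    fallback: bool = False

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        if self.selected.size == 0:
            raise ValueError("PC selection must never be empty")


@dataclass
class NodeClassifier:
    """A trained local decision unit attached to one tree node."""

    node_name: str
    kind: str  # {"linear", "one_class"}
    pc_indices: np.ndarray  # ascending indices into the shared PC scores
    estimator: object
    selection: PCSelection | None = field(default=None, repr=False)

    def score_and_classify(self, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Binary call and signed score for cells given shared PC scores.

        ``scores`` is a cells-by-components matrix in the *shared* component
        space; the node's own components are subset internally.  The signed
        score is the distance to the decision boundary: positive inside /
        on the positive side, zero exactly on the boundary.
        """
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] <= int(self.pc_indices.max()):
            raise ValueError(
                f"expected at least {int(self.pc_indices.max()) + 1} components, "
                f"got shape {scores.shape}"
            )
        z = scores[:, self.pc_indices]
        raw = self.estimator.decision_function(z)
        if self.kind == "linear":
            w = np.linalg.norm(np.ravel(self.estimator.coef_))
            signed = raw / w if w > 0 else raw
            call = raw > 0
        else:
            signed = raw
            call = self.estimator.predict(z) == 1
        return call, signed


def select_training_sets(
    tree: ClassificationTree, node: str, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Positive and negative cell indices for a node under the siblings policy.

    Returns
    -------
    (pos, neg) : integer index arrays into ``labels``.

    Raises
    ------
    ValueError
        If the node is the root or has no positive cells (untrainable).
    """
    labels = np.asarray(labels)
    tn = tree.node(node)
    if tn is tree.root:
        raise ValueError("the root carries no classifier")
    pos_labels = tree.subtree_labels(node)
    siblings = [c for c in tn.parent.children if c is not tn]
    if siblings:
        neg_labels = set()
        for sib in siblings:
            neg_labels |= tree.subtree_labels(sib.name)
    else:
        # no siblings: cells labelled as the parent itself (but not the node)
        neg_labels = {tn.parent.name}
    pos = np.flatnonzero(np.isin(labels, sorted(pos_labels)))
    neg = np.flatnonzero(np.isin(labels, sorted(neg_labels - pos_labels)))
    if pos.size == 0:
        raise ValueError(f"node {node!r} has no positive training cells")
    return pos, neg


def select_informative_pcs(
    pos: np.ndarray, neg: np.ndarray, alpha: float = 0.05
) -> PCSelection:
    """Welch two-sided t-test per component, Bonferroni threshold alpha/m.

    ``pos`` and ``neg`` are score matrices (cells x components) of the node's
    positive and negative cells in the shared component space.  When no
    component passes the corrected threshold, the five smallest-p components
    are selected instead, so the selection is never empty.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    neg = np.atleast_2d(np.asarray(neg, dtype=float))
    if pos.shape[1] != neg.shape[1]:
        raise ValueError("positive and negative scores differ in component count")
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError("need at least 2 samples per class for the t-test")
    m = pos.shape[1]
    p = stats.ttest_ind(pos, neg, axis=0, equal_var=False).pvalue
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical components
    selected = np.flatnonzero(p < alpha / m)
    fallback = selected.size == 0
    if fallback:
        selected = np.sort(np.argsort(p, kind="stable")[: min(5, m)])
    return PCSelection(
        alpha=alpha, n_components=m, p_values=p, selected=selected, fallback=fallback
    )


def fit_node_classifier(
    kind: str,
    positives: np.ndarray,
    negatives: np.ndarray | None = None,
    *,
    node_name: str = "",
    nu: float = 0.05,
    one_class_kernel: str = "rbf",
    random_state: int | None = 0,
    selection: PCSelection | None = None,
    pc_indices: np.ndarray | None = None,
) -> NodeClassifier:
    """Fit a local classifier of the given kind on (already subset) PC scores.

    ``positives``/``negatives`` must be expressed in the node's selected
    components.  ``pc_indices`` records which shared components those are
    (defaults to 0..k-1 when the caller already works in node space).
    """
    positives = np.atleast_2d(np.asarray(positives, dtype=float))
    if pc_indices is None:
        pc_indices = np.arange(positives.shape[1])
    pc_indices = np.asarray(pc_indices, dtype=int)
    if kind == "one_class":
        if positives.shape[0] < 2:
            raise ValueError("one_class requires at least 2 positive samples")
        est = OneClassSVM(nu=nu, kernel=one_class_kernel, gamma="scale")
        est.fit(positives)
    elif kind == "linear":
        if negatives is None or len(negatives) == 0:
            raise ValueError("linear requires non-empty negatives")
        negatives = np.atleast_2d(np.asarray(negatives, dtype=float))
        X = np.vstack([positives, negatives])
        if np.allclose(X, X[0]):
            raise ValueError(
                "degenerate training data: all points identical across classes"
            )
        y = np.concatenate(
            [np.ones(len(positives)), -np.ones(len(negatives))]
        )
        est = LinearSVC(
            dual="auto", tol=1e-4, max_iter=5000, random_state=random_state
        )
        est.fit(X, y)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return NodeClassifier(
        node_name=node_name,
        kind=kind,
        pc_indices=pc_indices,
        estimator=est,
        selection=selection,
    )


def score_and_classify(
    model: NodeClassifier, cells: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Binary call plus signed score per cell (see NodeClassifier)."""
    return model.score_and_classify(cells)
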