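"""Progressive learning of a classification tree from multiple datasets.

Iteration 1 trains a flat classifier for each of the first two datasets,
cross-predicts, matches the labels reciprocally and updates the first
dataset's tree.  Every following iteration adds one dataset: a flat
classifier is trained on the new dataset, the current tree is retrained on
all pre-existing datasets pooled (their labels rewritten to the tree's node
names through the synonym/label maps), the labels are cross-predicted and
matched, and the tree is updated again.

All datasets must live in the same (batch-aligned) expression space; the
alignment itself is upstream of this package.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

from .classifier import HierarchicalClassifier
from .matching import match_labels
from .tree import ClassificationTree
from .update import UpdateReport, update_from_match

logger = logging.getLogger(__name__)


class ProgressiveTreeLearner(BaseEstimator):
    """Learn a classification tree by reciprocally matching dataset labels.

    Parameters
    ----------
    kind : {"linear", "one_class"}
        Local classifier family used throughout.  The linear classifier is
        more accurate; the one-class boundary copes better with populations
        missing from individual datasets.
    match_threshold : float, default=0.25
        Binarisation threshold of the reciprocal matching step.
    n_components, alpha, q, nu, one_class_kernel, reject_reconstruction,
    random_state :
        Passed through to :class:`~celltree.classifier.HierarchicalClassifier`.
    fit_final : bool, default=True
        After the last update, train ``classifier_`` on all datasets pooled.

    Attributes
    ----------
    tree_ : ClassificationTree
        The learned hierarchy.
    reports_ : list[UpdateReport]
        One report per added dataset (scenario log, label maps).
    label_maps_ : list[dict]
        Per dataset, original label -> tree node name (None when a population
        could not be added due to a complex scenario; its cells are excluded
        from later pooled training).
    classifier_ : HierarchicalClassifier, optional
        Final hierarchy trained on all pooled datasets (when ``fit_final``).
    """

    def __init__(
        self,
        kind="linear",
        match_threshold=0.25,
        n_components=100,
        alpha=0.05,
        q=0.99,
        nu=0.05,
        one_class_kernel="rbf",
        reject_reconstruction=True,
        random_state=0,
        fit_final=True,
    ):
        self.kind = kind
        self.match_threshold = match_threshold
        self.n_components = n_components
        self.alpha = alpha
        self.q = q
        self.nu = nu
        self.one_class_kernel = one_class_kernel
        self.reject_reconstruction = reject_reconstruction
        self.random_state = random_state
        self.fit_final = fit_final

    def _make_classifier(self, tree) -> HierarchicalClassifier:
        return HierarchicalClassifier(
            tree=tree,
            kind=self.kind,
            n_components=self.n_components,
            alpha=self.alpha,
            q=self.q,
            nu=self.nu,
            one_class_kernel=self.one_class_kernel,
            reject_reconstruction=self.reject_reconstruction,
            random_state=self.random_state,
        )

    def _pooled(self, datasets, upto: int):
        """Pool datasets[:upto] with labels mapped to tree node names."""
        xs, ys = [], []
        for (X, y), lm in zip(datasets[:upto], self.label_maps_[:upto]):
            y = np.asarray(y, dtype=object).astype(str)
            mapped = np.array([lm.get(lab) for lab in y], dtype=object)
            keep = np.array([m is not None for m in mapped])
            xs.append(np.asarray(X)[keep])
            ys.append(mapped[keep].astype(str))
        return np.vstack(xs), np.concatenate(ys)

    def fit(self, datasets, y=None):
        """Learn the tree from a sequence of ``(X, labels)`` datasets."""
        datasets = list(datasets)
        if len(datasets) < 2:
            raise ValueError("progressive learning needs at least 2 datasets")
        X0, y0 = datasets[0]
        y0 = np.asarray(y0, dtype=object).astype(str)
        self.tree_ = ClassificationTree.flat(np.unique(y0))
        self.label_maps_ = [{lab: lab for lab in np.unique(y0)}]
        self.reports_: list[UpdateReport] = []

        for k in range(1, len(datasets)):
            Xk, yk = datasets[k]
            yk = np.asarray(yk, dtype=object).astype(str)
            X1, y1 = self._pooled(datasets, k)
            logger.info(
                "iteration %d: adding dataset with populations %s",
                k, sorted(set(yk)),
            )
            try:
                h1 = self._make_classifier(self.tree_).fit(X1, y1)
                h2 = self._make_classifier(None).fit(Xk, yk)
            except ValueError as exc:
                raise ValueError(
                    f"untrainable population while adding dataset {k}: {exc}"
                ) from exc
            match = match_labels(
                h1, h2, X1, y1, Xk, yk, threshold=self.match_threshold
            )
            self.tree_, report = update_from_match(self.tree_, match)
            # populations never seen by any scenario keep their own name only
            # if they were actually added; otherwise they are dropped
            lm = {
                lab: report.label_map.get(lab)
                for lab in np.unique(yk)
            }
            self.label_maps_.append(lm)
            self.reports_.append(report)

        if self.fit_final:
            Xall, yall = self._pooled(datasets, len(datasets))
            self.classifier_ = self._make_classifier(self.tree_).fit(Xall, yall)
        return self


def learn_tree_progressive(
    datasets,
    kind: str = "linear",
    threshold: float = 0.25,
    **kwargs,
) -> ClassificationTree:
    """Functional wrapper: learn and return the final classification tree."""
    learner = ProgressiveTreeLearner(
        kind=kind, match_threshold=threshold, fit_final=False, **kwargs
    )
    return learner.fit(datasets).tree_
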