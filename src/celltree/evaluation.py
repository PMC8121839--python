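"""Evaluation metrics for hierarchical cell-identity prediction.

The hierarchical F1-score credits partially correct predictions: for each
cell the predicted node and its ancestors (root excluded) form the set P_i,
the true node and its ancestors the set T_i, and

    hP = sum_i |P_i ∩ T_i| / sum_i |P_i|
    hR = sum_i |P_i ∩ T_i| / sum_i |T_i|
    HF1 = 2 hP hR / (hP + hR).

A rejected cell contributes an empty P_i, so rejection hurts recall but not
precision.  The median F1-score is the median over populations of the
per-population F1, computed after discarding cells whose prediction is a
rejection or an internal node.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .classifier import HierarchicalClassifier
from .tree import REJECTED, ClassificationTree


def _ancestry_set(tree: ClassificationTree, label: str) -> set[str]:
    return {label, *tree.ancestors(label)}


def hierarchical_f1(
    true_labels, predicted_labels, tree: ClassificationTree
) -> tuple[float, float, float]:
    """Hierarchical precision, recall and F1 over predicted/true ancestor sets."""
    true_labels = np.asarray(true_labels, dtype=object).astype(str)
    predicted_labels = np.asarray(predicted_labels, dtype=object).astype(str)
    if true_labels.size == 0:
        raise ValueError("empty input")
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors differ in length")
    cache: dict[str, set[str]] = {}

    def sets(label: str) -> set[str]:
        if label not in cache:
            cache[label] = _ancestry_set(tree, label)
        return cache[label]

    overlap = sum_p = sum_t = 0
    for t, p in zip(true_labels, predicted_labels):
        T = sets(t)
        if p == REJECTED:
            P: set[str] = set()
        else:
            P = sets(p)
        overlap += len(P & T)
        sum_p += len(P)
        sum_t += len(T)
    hP = overlap / sum_p if sum_p else 0.0
    hR = overlap / sum_t  # T_i is never empty
    hf1 = 2 * hP * hR / (hP + hR) if (hP + hR) else 0.0
    return hP, hR, hf1


def median_f1(
    true_labels, predicted_labels, tree: ClassificationTree | None = None
) -> float:
    """Median per-population F1; rejected and internal predictions excluded."""
    true_labels = np.asarray(true_labels, dtype=object).astype(str)
    predicted_labels = np.asarray(predicted_labels, dtype=object).astype(str)
    if true_labels.size == 0:
        raise ValueError("empty input")
    drop = {REJECTED}
    if tree is not None:
        drop |= set(tree.internal_names())
    keep = ~np.isin(predicted_labels, sorted(drop))
    if not keep.any():
        raise ValueError("no population has any counted cell")
    yt, yp = true_labels[keep], predicted_labels[keep]
    pops = sorted(set(yt))
    scores = f1_score(yt, yp, labels=pops, average=None, zero_division=0.0)
    return float(np.median(scores))


def kfold_evaluate(
    data,
    labels,
    tree=None,
    kind: str = "linear",
    k: int = 10,
    seed: int = 0,
    **classifier_kwargs,
) -> pd.DataFrame:
    """Stratified k-fold cross-validation of the hierarchical classifier.

    Returns one row per fold with hierarchical precision/recall/F1, median
    F1, and the fractions of rejected and internal-node predictions.
    """
    data = np.asarray(data)
    labels = np.asarray(labels, dtype=object).astype(str)
    if k < 2:
        raise ValueError("k must be at least 2")
    counts = pd.Series(labels).value_counts()
    starving = counts[counts < k]
    if len(starving):
        raise ValueError(
            f"populations with fewer cells than folds: "
            f"{sorted(starving.index.tolist())}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(data, labels)):
        h = HierarchicalClassifier(
            tree=tree, kind=kind, random_state=seed, **classifier_kwargs
        ).fit(data[tr], labels[tr])
        pred = h.predict(data[te])
        hp, hr, hf1 = hierarchical_f1(labels[te], pred, h.tree_)
        internal = set(h.tree_.internal_names())
        rows.append(
            {
                "fold": fold,
                "hP": hp,
                "hR": hr,
                "HF1": hf1,
                "median_F1": median_f1(labels[te], pred, h.tree_),
                "frac_rejected": float(np.mean(pred == REJECTED)),
                "frac_internal": float(
                    np.mean([p in internal for p in pred])
                ),
            }
        )
    return pd.DataFrame(rows).set_index("fold")
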