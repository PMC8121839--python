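"""Reciprocal label matching between two annotated datasets.

The classifier trained on dataset D1 predicts the labels of D2 and vice
versa.  Each direction yields a confusion matrix C whose rows are the true
populations of one dataset and whose columns are the possible predictions of
the other dataset's classifier (all of its tree's node names plus
``"rejected"``).  Rows are normalised to fractions,

    NC_ij = C_ij / sum_j C_ij,

and binarised: per row, the fractions are ranked, the highest becomes a
match, and the walk down the ranking keeps marking matches while the gap to
the preceding (higher) fraction stays below a threshold (default 0.25).
The two binary matrices combine into the matching matrix

    X = BC1^T + BC2,

whose rows are D2's populations and columns D1's populations; X_ij = 2 is a
reciprocal match, 1 a one-sided match, 0 no match.  Matches to the other
tree's internal nodes that carry no training cells and to "rejected" stay in
the binary matrices as bookkeeping (they drive new-population detection) but
are not part of the population-by-population block of X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import REJECTED


def cross_prediction_confusion(
    true_labels, predicted_labels, prediction_vocabulary
) -> pd.DataFrame:
    """Integer confusion matrix of true populations vs predicted labels.

    Columns are the prediction vocabulary (the other tree's node names) plus
    ``"rejected"``; rows are the unique true labels, sorted.  Predictions
    outside the vocabulary raise an error.
    """
    true_labels = np.asarray(true_labels, dtype=object).astype(str)
    predicted_labels = np.asarray(predicted_labels, dtype=object).astype(str)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("true and predicted label vectors differ in length")
    vocab = list(dict.fromkeys(prediction_vocabulary))
    if REJECTED not in vocab:
        vocab.append(REJECTED)
    unknown = sorted(set(predicted_labels) - set(vocab))
    if unknown:
        raise ValueError(f"predictions outside the vocabulary: {unknown}")
    rows = sorted(set(true_labels))
    counts = pd.crosstab(
        pd.Series(true_labels, name="true"),
        pd.Series(predicted_labels, name="predicted"),
    )
    return counts.reindex(index=rows, columns=vocab, fill_value=0).astype(int)


def normalize_confusion(C: pd.DataFrame) -> pd.DataFrame:
    """Row-stochastic confusion matrix (fraction of each population)."""
    C = pd.DataFrame(C).astype(float)
    sums = C.sum(axis=1)
    empty = sums[sums <= 0]
    if len(empty):
        raise ValueError(
            f"populations without any cells: {sorted(empty.index.tolist())}"
        )
    return C.div(sums, axis=0)


def binarize_matches(NC: pd.DataFrame, threshold: float = 0.25) -> pd.DataFrame:
    """Threshold-ranked binarisation of a row-stochastic matrix.

    Per row: rank the fractions descending; the highest becomes 1; walking
    down the ranking, each next fraction is also set to 1 while its gap to
    the preceding (higher) fraction is strictly below ``threshold``; the
    first gap >= threshold stops the walk.  Zero fractions never match.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    NC = pd.DataFrame(NC).astype(float)
    mat = NC.to_numpy()
    out = np.zeros(mat.shape, dtype=int)
    for i in range(mat.shape[0]):
        vals = mat[i]
        order = np.argsort(-vals, kind="stable")
        prev = None
        for j in order:
            v = vals[j]
            if v <= 0:
                break
            if prev is not None and (prev - v) >= threshold:
                break
            out[i, j] = 1
            prev = v
    return pd.DataFrame(out, index=NC.index, columns=NC.columns)


def build_matching_matrix(
    BC1: pd.DataFrame,
    BC2: pd.DataFrame,
    populations_D1=None,
    populations_D2=None,
) -> pd.DataFrame:
    """Matching matrix X = BC1^T + BC2 over the population-by-population block.

    ``BC1`` rows are D1 populations (columns: D2's vocabulary); ``BC2`` rows
    are D2 populations.  The result has D2 populations as rows and D1
    populations as columns, with entries in {0, 1, 2}.
    """
    pops1 = list(populations_D1) if populations_D1 is not None else list(BC1.index)
    pops2 = list(populations_D2) if populations_D2 is not None else list(BC2.index)
    missing1 = [p for p in pops1 if p not in BC1.index or p not in BC2.columns]
    missing2 = [p for p in pops2 if p not in BC2.index or p not in BC1.columns]
    if missing1 or missing2:
        raise ValueError(
            f"populations missing from the binary matrices: {missing1 + missing2}"
        )
    a = BC1.loc[pops1, pops2].T.to_numpy()
    b = BC2.loc[pops2, pops1].to_numpy()
    X = pd.DataFrame(a + b, index=pops2, columns=pops1, dtype=int)
    if not X.isin([0, 1, 2]).all().all():  # pragma: no cover - defensive
        raise ValueError("matching matrix entries must be 0, 1 or 2")
    return X


@dataclass
class MatchResult:
    """Full bookkeeping of one reciprocal matching step."""

    X: pd.DataFrame  # rows: D2 populations, cols: D1 populations
    C1: pd.DataFrame
    C2: pd.DataFrame
    BC1: pd.DataFrame
    BC2: pd.DataFrame

    @property
    def rejected_d2(self) -> pd.Series:
        """Per D2 population: was it matched to rejection by D1's classifier?"""
        return self.BC2[REJECTED] == 1


def match_labels(
    h1, h2, X1, y1, X2, y2, threshold: float = 0.25
) -> MatchResult:
    """Cross-predict two labelled datasets and build the matching matrix.

    ``h1``/``h2`` are fitted :class:`~celltree.classifier.HierarchicalClassifier`
    instances for datasets (``X1``, ``y1``) and (``X2``, ``y2``).
    """
    y1 = np.asarray(y1, dtype=object).astype(str)
    y2 = np.asarray(y2, dtype=object).astype(str)
    pred1 = h2.predict(X1)  # D1 cells labelled by D2's classifier
    pred2 = h1.predict(X2)
    C1 = cross_prediction_confusion(y1, pred1, h2.tree_.nonroot_names())
    C2 = cross_prediction_confusion(y2, pred2, h1.tree_.nonroot_names())
    BC1 = binarize_matches(normalize_confusion(C1), threshold)
    BC2 = binarize_matches(normalize_confusion(C2), threshold)
    pops1 = [p for p in C1.index if p in BC2.columns]
    pops2 = [p for p in C2.index if p in BC1.columns]
    X = build_matching_matrix(BC1, BC2, pops1, pops2)
    return MatchResult(X=X, C1=C1, C2=C2, BC1=BC1, BC2=BC2)
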