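"""Reconstruction-error rejection of out-of-distribution cells.

A new, unknown population is not used to learn the PCA transformation of the
training data, so it is poorly represented by the retained components and its
reconstruction error — the Euclidean distance of a cell to the plane spanned
by the retained components — is high.  Thresholding that error rejects such
cells before any classifier is consulted.

The threshold is calibrated by nested five-fold cross-validation: for each
fold a PCA is fitted on the training split, the held-out split is projected
and back-projected, and the q-th percentile (default q = 0.99) of the
held-out per-cell errors is recorded.  The threshold is the median of the
five fold percentiles, so on in-distribution data roughly a fraction 1 - q of
cells exceeds it (the controllable false-negative rate).  Finally a PCA is
refitted on the whole dataset to obtain the projection applied to new cells.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, validate_data


class PCAReconstructionRejector(OutlierMixin, BaseEstimator):
    """Reject cells whose distance to the training-data PC plane is too large.

    Parameters
    ----------
    n_components : int, default=100
        Number of principal components retained.  Capped at the available
        rank of each training split.
    q : float, default=0.99
        Percentile (in (0, 1)) of held-out reconstruction errors used per
        fold; ``1 - q`` is the expected in-distribution rejection rate.
    n_folds : int, default=5
        Folds of the nested cross-validation.
    random_state : int or None, default=0
        Seeds the fold shuffling and the randomised PCA solver.

    Attributes
    ----------
    pca_ : sklearn.decomposition.PCA
        Projection refitted on the full training data.
    threshold_ : float
        Calibrated reconstruction-error cutoff (median of fold percentiles).
    fold_percentiles_ : ndarray of shape (n_folds,)
    """

    def __init__(self, n_components=100, q=0.99, n_folds=5, random_state=0):
        self.n_components = n_components
        self.q = q
        self.n_folds = n_folds
        self.random_state = random_state

    def _make_pca(self, n_samples: int, n_features: int) -> PCA:
        k = int(min(self.n_components, n_samples, n_features))
        return PCA(
            n_components=k,
            svd_solver="randomized",
            random_state=self.random_state,
        )

    @staticmethod
    def _errors(pca: PCA, X: np.ndarray) -> np.ndarray:
        recon = pca.inverse_transform(pca.transform(X))
        return np.linalg.norm(X - recon, axis=1)

    def fit(self, X, y=None):
        if not (isinstance(self.q, numbers.Real) and 0.0 < self.q < 1.0):
            raise ValueError(f"q must lie in (0, 1), got {self.q!r}")
        X = validate_data(self, X, ensure_min_samples=self.n_folds)
        kf = KFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        percentiles = []
        for train_idx, test_idx in kf.split(X):
            pca = self._make_pca(len(train_idx), X.shape[1])
            pca.fit(X[train_idx])
            err = self._errors(pca, X[test_idx])
            percentiles.append(np.percentile(err, 100.0 * self.q))
        self.fold_percentiles_ = np.asarray(percentiles)
        self.threshold_ = float(np.median(self.fold_percentiles_))
        self.pca_ = self._make_pca(X.shape[0], X.shape[1]).fit(X)
        return self

    def reconstruction_error(self, X) -> np.ndarray:
        """Per-cell distance to the plane spanned by the retained components."""
        check_is_fitted(self, "pca_")
        X = validate_data(self, X, reset=False)
        return self._errors(self.pca_, X)

    def decision_function(self, X) -> np.ndarray:
        """Positive for accepted (in-distribution) cells, negative for rejected."""
        return self.threshold_ - self.reconstruction_error(X)

    def predict(self, X) -> np.ndarray:
        """sklearn outlier convention: +1 accepted, -1 rejected."""
        return np.where(self.decision_function(X) >= 0, 1, -1)


def learn_rejection_threshold(
    data: np.ndarray,
    q: float = 0.99,
    *,
    n_components: int = 100,
    n_folds: int = 5,
    random_state: int | None = 0,
) -> PCAReconstructionRejector:
    """Calibrate a reconstruction-error rejection model on training data."""
    return PCAReconstructionRejector(
        n_components=n_components, q=q, n_folds=n_folds, random_state=random_state
    ).fit(data)


def reconstruction_error(model: PCAReconstructionRejector, cells) -> np.ndarray:
    """Per-cell reconstruction error under a fitted rejection model."""
    return model.reconstruction_error(cells)
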