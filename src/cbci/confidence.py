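"""Neural confidence feature: spatio-temporal PCA + LARS regression.

Every (channel, time-sample) pair of a response-locked epoch is treated as a
separate variable, so a 64x24 epoch flattens (channel-major) to a length-1536
vector.  PCA on those vectors yields an eigenvalue-ranked orthonormal basis;
the scores on the top 24 components (a 1-to-64 reduction) feed a least-angle
regression trained to predict +1 for trials answered incorrectly and -1 for
trials answered correctly.  The regression output, the *neural feature* nf,
is a per-trial scalar proxy for (inverse) decision confidence: values nearer
+1 flag low-confidence, likely-wrong decisions.

Out-of-fold nf values come from k-fold cross-validation in which both the
PCA basis and the LARS coefficients are refit on each training split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.linear_model import Lars
from sklearn.utils.validation import check_is_fitted

from .preprocess import Epoch

N_COMPONENTS_DEFAULT = 24


def _as_matrix(epochs) -> np.ndarray:
    """Flatten epochs to (n_samples, n_features), channel-major."""
    if isinstance(epochs, np.ndarray):
        arr = epochs
    else:
        arr = np.stack([e.voltages if isinstance(e, Epoch) else np.asarray(e) for e in epochs])
    if arr.ndim == 3:
        arr = arr.reshape(arr.shape[0], -1)
    return np.asarray(arr, dtype=float)


class SpatioTemporalPCA(TransformerMixin, BaseEstimator):
    """PCA over flattened (channel x time) epoch vectors.

    Parameters
    ----------
    n_components : int
        Number of leading components returned by :meth:`transform`.
    full_basis : bool
        If True, keep all ``n_features`` eigenvectors (a complete orthonormal
        basis, with zero eigenvalues past the data rank); otherwise keep only
        ``min(n_samples, n_features)`` vectors, which is cheaper and enough
        for feature extraction.

    Attributes
    ----------
    mean_ : (n_features,) training mean of the flattened epochs.
    components_ : (n_kept, n_features) orthonormal eigenvectors, eigenvalue-ranked.
    eigenvalues_ : matching covariance eigenvalues, descending.
    """

    def __init__(self, n_components: int = N_COMPONENTS_DEFAULT, full_basis: bool = False):
        self.n_components = n_components
        self.full_basis = full_basis

    def fit(self, X, y=None):
        X = _as_matrix(X)
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 training epochs")
        if n < self.n_components:
            warnings.warn(
                f"only {n} epochs for {self.n_components} components; "
                "trailing components have zero eigenvalue",
                stacklevel=2,
            )
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        _, s, Vt = np.linalg.svd(Xc, full_matrices=self.full_basis)
        eig = np.zeros(Vt.shape[0])
        eig[: len(s)] = s**2 / (n - 1)
        # deterministic sign: largest-magnitude loading positive
        flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = Vt * flip[:, None]
        self.eigenvalues_ = eig
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = _as_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("epoch shape does not match the fitted basis")
        k = min(self.n_components, self.components_.shape[0])
        return (X - self.mean_) @ self.components_[:k].T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        scores = np.asarray(scores, dtype=float)
        k = scores.shape[-1]
        return scores @ self.components_[:k] + self.mean_


class LarsConfidence(RegressorMixin, BaseEstimator):
    """Least-angle regression of +/-1 correctness labels on epoch features.

    LARS is run for ``max_steps`` variable entries (by default all 24
    components, where the path endpoint coincides with ordinary least
    squares).  ``predict`` returns the scalar neural feature nf.
    """

    def __init__(self, max_steps: int = N_COMPONENTS_DEFAULT):
        self.max_steps = max_steps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("labels must be -1 (correct) or +1 (incorrect)")
        if np.ptp(y) == 0:  # degenerate: one class only
            self.coef_ = np.zeros(X.shape[1])
            self.intercept_ = float(y[0])
            self.active_ = []
            return self
        with warnings.catch_warnings():
            # collinear/constant features trigger benign path warnings
            warnings.simplefilter("ignore")
            lars = Lars(n_nonzero_coefs=self.max_steps, fit_intercept=True)
            lars.fit(X, y)
        self.coef_ = lars.coef_
        self.intercept_ = float(lars.intercept_)
        self.active_ = list(np.flatnonzero(self.coef_))
        self.entry_order_ = list(lars.active_)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


@dataclass(frozen=True)
class FoldScheme:
    """Deterministic interleaved k-fold assignment: trial t -> fold t mod k."""

    k: int
    assignment: np.ndarray

    @classmethod
    def interleaved(cls, n_trials: int, k: int) -> "FoldScheme":
        if k < 2 or n_trials % k != 0:
            raise ValueError(
                f"k must be a divisor of {n_trials} greater than 1; "
                f"admissible values: {admissible_folds(n_trials)}"
            )
        return cls(k=k, assignment=np.arange(n_trials) % k)


def admissible_folds(n_trials: int) -> list[int]:
    """Divisors of the trial count usable as fold counts (excluding 1)."""
    return [d for d in range(2, n_trials + 1) if n_trials % d == 0]


def crossvalidated_nf(
    epochs,
    labels: np.ndarray,
    k: int = 16,
    n_components: int = N_COMPONENTS_DEFAULT,
    max_steps: int = N_COMPONENTS_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold nf for every trial.

    Per fold, the PCA basis and LARS coefficients are fit on the training
    trials only and applied to the held-out trials.  Returns ``(nf, fold_id)``
    arrays aligned with the input trial order.
    """
    X = _as_matrix(epochs)
    labels = np.asarray(labels, dtype=float)
    if len(labels) != X.shape[0]:
        raise ValueError("labels and epochs must align")
    scheme = FoldScheme.interleaved(X.shape[0], k)
    nf = np.full(X.shape[0], np.nan)
    for fold in range(k):
        test = scheme.assignment == fold
        train = ~test
        pca = SpatioTemporalPCA(n_components=n_components).fit(X[train])
        model = LarsConfidence(max_steps=max_steps).fit(pca.transform(X[train]), labels[train])
        nf[test] = model.predict(pca.transform(X[test]))
    return nf, scheme.assignment.copy()
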