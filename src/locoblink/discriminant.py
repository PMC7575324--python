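"""Gait-parameter discriminant mapping: z-score -> PCA -> LDA.

Each observation is one animal locomoting at one speed; features are
z-scored gait parameters.  Because LDA assumes an uncorrelated feature
space, PCA (eigendecomposition of the data covariance matrix, descending
eigenvalues) is applied first and only the leading components are passed
to the LDA.  The contribution of each original gait parameter to the
discriminant axes is recovered by multiplying the PCA mapping by the LDA
mapping.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted


class GaitDiscriminant(BaseEstimator, TransformerMixin):
    """Supervised low-dimensional embedding of gait-parameter tables.

    Parameters
    ----------
    n_pcs : int, default 10
        Number of principal components retained as LDA input.  Must be
        smaller than the number of observations.

    Attributes
    ----------
    mean_, scale_ : per-feature z-scoring statistics.
    components_ : (n_features, n_pcs) PCA mapping (covariance eigenvectors).
    eigenvalues_ : descending covariance eigenvalues (all of them).
    explained_variance_ratio_ : fraction of total variance per retained PC.
    contributions_ : (n_features, n_ld) back-projected feature
        contributions to the discriminant axes (PCA map x LDA map).
    classes_ : group labels.
    feature_names_ : retained feature names (constant features dropped).
    """

    def __init__(self, n_pcs: int = 10):
        self.n_pcs = n_pcs

    def _validate(self, X):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(float)
        else:
            X = np.asarray(X, float)
            names = [f"feature_{i}" for i in range(X.shape[1])]
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature table")
        return X, names

    def fit(self, X, y):
        X, names = self._validate(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 groups")
        n_obs = X.shape[0]
        if self.n_pcs >= n_obs:
            raise ValueError(
                f"n_pcs={self.n_pcs} must be smaller than the number of "
                f"observations ({n_obs})"
            )
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [n for n, k in zip(names, keep) if not k]
            warnings.warn(
                f"dropping constant features: {dropped}", UserWarning, stacklevel=2
            )
        self._keep_idx = np.flatnonzero(keep)
        self._n_features_in = keep.size
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
        self.feature_names_ = names
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        Z = (X - self.mean_) / self.scale_

        cov = np.cov(Z, rowvar=False, ddof=1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals = eigvals[order]
        eigvecs = eigvecs[:, order]
        n_pcs = min(self.n_pcs, len(eigvals))
        self.eigenvalues_ = eigvals
        self.components_ = eigvecs[:, :n_pcs]
        self.explained_variance_ratio_ = eigvals[:n_pcs] / eigvals.sum()

        scores = Z @ self.components_
        self._lda = LinearDiscriminantAnalysis()
        self._lda.fit(scores, y)
        self.classes_ = self._lda.classes_
        self.contributions_ = self.components_ @ self._lda.scalings_
        return self

    def _scores(self, X):
        X, _ = self._validate(X)
        if X.shape[1] == self._n_features_in:
            X = X[:, self._keep_idx]
        elif X.shape[1] != len(self.mean_):
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self._n_features_in}"
            )
        Z = (X - self.mean_) / self.scale_
        return Z @ self.components_

    def transform(self, X):
        """Project observations onto the discriminant (LD) axes."""
        check_is_fitted(self, "contributions_")
        return self._lda.transform(self._scores(X))

    def predict(self, X):
        check_is_fitted(self, "contributions_")
        return self._lda.predict(self._scores(X))

    def contributions_frame(self) -> pd.DataFrame:
        """Per-feature contributions to each LD axis as a tidy DataFrame."""
        check_is_fitted(self, "contributions_")
        cols = [f"LD{i + 1}" for i in range(self.contributions_.shape[1])]
        return pd.DataFrame(self.contributions_, index=self.feature_names_,
                            columns=cols)


def discriminant_map(features, labels, n_pcs: int = 10):
    """Fit the z-score -> PCA -> LDA mapping; return (projections, contributions).

    Thin functional wrapper over :class:`GaitDiscriminant`.
    """
    est = GaitDiscriminant(n_pcs=n_pcs).fit(features, labels)
    return est.transform(features), est.contributions_frame()
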