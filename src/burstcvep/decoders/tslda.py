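"""Riemannian tangent-space LDA decoder.

xDAWN spatial filtering (fitted on flash epochs), an augmented
"super-covariance" per epoch — the filtered flash prototype stacked over the
filtered epoch, summarized by an 8x8 Ledoit-Wolf covariance — projected to
the tangent space at the training-set Riemannian mean, and a linear
discriminant on the 36 tangent coordinates.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ..geometry import lw_covariances, riemannian_mean, tangent_vectors
from ..spatial import Xdawn

__all__ = ["TSLDAClassifier"]


class TSLDAClassifier(BaseEstimator, ClassifierMixin):
    """xDAWN + augmented covariance + tangent space + shrinkage LDA.

    Deterministic given its inputs; ``seed`` is accepted for contract
    parity with the neural decoders but unused.
    """

    def __init__(
        self,
        n_components: int = 4,
        seed: int = 0,
        mean_tol: float = 1e-7,
        mean_max_iter: int = 100,
    ):
        self.n_components = n_components
        self.seed = seed
        self.mean_tol = mean_tol
        self.mean_max_iter = mean_max_iter

    def _features(self, X: np.ndarray) -> np.ndarray:
        Z = self.xdawn_.transform(X)
        proto = np.broadcast_to(self.prototype_, (len(Z),) + self.prototype_.shape)
        aug = np.concatenate([proto, Z], axis=1)
        covs = lw_covariances(aug)
        return tangent_vectors(covs, self.mean_)

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.xdawn_ = Xdawn(n_components=self.n_components).fit(X, y)
        Z = self.xdawn_.transform(X)
        self.prototype_ = Z[y == 1].mean(axis=0)
        proto = np.broadcast_to(self.prototype_, Z.shape[:1] + self.prototype_.shape)
        covs = lw_covariances(np.concatenate([proto, Z], axis=1))
        self.mean_ = riemannian_mean(
            covs, tol=self.mean_tol, max_iter=self.mean_max_iter
        )
        feats = tangent_vectors(covs, self.mean_)
        self.lda_ = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        self.lda_.fit(feats, y)
        self.classes_ = self.lda_.classes_
        return self

    def predict_proba(self, X):
        return self.lda_.predict_proba(self._features(np.asarray(X)))

    def predict(self, X):
        return self.lda_.predict(self._features(np.asarray(X)))

    def finetune(self, X, y, X_extra=None, y_extra=None):
        """Closest analogue of fine-tuning for a closed-form model.

        No gradient notion exists, so the tangent reference and the LDA are
        refit on the pooled calibration data (optionally together with the
        pretraining data), keeping the fitted xDAWN filters.
        """
        X = np.asarray(X)
        y = np.asarray(y)
        if X_extra is not None:
            X = np.concatenate([X_extra, X])
            y = np.concatenate([y_extra, y])
        Z = self.xdawn_.transform(X)
        self.prototype_ = Z[y == 1].mean(axis=0)
        proto = np.broadcast_to(self.prototype_, Z.shape[:1] + self.prototype_.shape)
        covs = lw_covariances(np.concatenate([proto, Z], axis=1))
        self.mean_ = riemannian_mean(
            covs, tol=self.mean_tol, max_iter=self.mean_max_iter
        )
        feats = tangent_vectors(covs, self.mean_)
        self.lda_ = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        self.lda_.fit(feats, y)
        return self
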