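"""Participant-specific spatial preprocessing.

The "complete" preprocessing chain: xDAWN spatial filtering (generalized
eigenvalue problem maximizing evoked-response variance against total
variance), super-epoch construction (epoch components stacked with the
spatially filtered average target response), Ledoit-Wolf covariances and
Riemannian-mean alignment.  All fits use calibration/training data only.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import invsqrtm_spd, lw_covariances, riemannian_mean
from .preprocess import EpochSet

__all__ = ["Xdawn", "SuperEpochBuilder", "RiemannianAlignment", "CompletePreprocessor"]


class Xdawn(BaseEstimator, TransformerMixin):
    """xDAWN spatial filter for flash-evoked responses.

    Estimates the evoked response by least squares with a Toeplitz design
    over the continuous training record (``fit_records``) or by target-epoch
    averaging (``fit`` on epochs, equivalent here because the ~0.35 s
    refractory gap prevents response overlap), then solves the generalized
    eigenproblem  C_evoked u = lambda C_total u  and keeps the top
    ``n_components`` filters.

    Attributes
    ----------
    filters_ : (n_channels, n_components) unit-norm filter columns, ordered
        by decreasing evoked-to-total variance ratio.
    patterns_ : (n_channels, n_components) corresponding forward patterns.
    evoked_ : (n_components, n_samples) spatially filtered evoked response,
        sign-normalized so each component's extremum is positive.
    eigenvalues_ : evoked-variance ratios of the kept components.
    """

    def __init__(self, n_components: int = 4, reg: float = 1e-9):
        self.n_components = n_components
        self.reg = reg

    # -- fitting routes ----------------------------------------------------
    def fit(self, X, y):
        """Fit from epochs (n, channels, samples) and binary labels."""
        X = np.asarray(X)
        y = np.asarray(y)
        if not ((y == 1).any() and (y == 0).any()):
            raise ValueError("both labels must be present")
        erp = X[y == 1].mean(axis=0)  # channels x samples
        n_total = X.shape[0] * X.shape[2]
        c_evoked = erp @ erp.T / erp.shape[1]
        flat = X.transpose(1, 0, 2).reshape(X.shape[1], -1)
        c_total = flat @ flat.T / n_total
        return self._solve(c_evoked, c_total, erp)

    def fit_records(self, records, onsets, n_samples_erp: int):
        """Fit from continuous records with flash-onset sample indices.

        ``records``: list of (channels, L) arrays; ``onsets``: list of int
        arrays of flash start samples.  The evoked response solves
        ``min ||X - D A||`` with D the 0/1 Toeplitz onset design.
        """
        nt = n_samples_erp
        n_ch = records[0].shape[0]
        dtd = np.zeros((nt, nt))
        dtx = np.zeros((nt, n_ch))
        c_total = np.zeros((n_ch, n_ch))
        n_total = 0
        for rec, ons in zip(records, onsets):
            L = rec.shape[1]
            ons = np.asarray(ons, dtype=int)
            ons = ons[ons + nt <= L]
            for i in ons:
                for j in ons:
                    lo = abs(int(i) - int(j))
                    if lo < nt:
                        if i <= j:
                            k = j - i
                            dtd[np.arange(nt - k), np.arange(k, nt)] += 1
                        else:
                            k = i - j
                            dtd[np.arange(k, nt), np.arange(nt - k)] += 1
                dtx[:, :] += rec[:, i : i + nt].T
            c_total += rec @ rec.T
            n_total += L
        A = linalg.solve(dtd + self.reg * np.eye(nt), dtx, assume_a="pos")
        erp = A.T  # channels x samples
        c_evoked = (A.T @ dtd @ A) / n_total  # covariance of the D A signal part
        c_total = c_total / n_total
        return self._solve(c_evoked, c_total, erp)

    def _solve(self, c_evoked, c_total, erp):
        n_ch = c_total.shape[0]
        if self.n_components > n_ch:
            raise ValueError("n_components cannot exceed channel count")
        c_total = c_total + self.reg * np.trace(c_total) * np.eye(n_ch)
        try:
            w, V = linalg.eigh(c_evoked, c_total)
        except linalg.LinAlgError as err:  # pragma: no cover
            raise linalg.LinAlgError(f"singular total covariance: {err}") from err
        order = np.argsort(w)[::-1][: self.n_components]
        U = V[:, order]
        U = U / np.linalg.norm(U, axis=0, keepdims=True)
        # sign convention: evoked extremum positive per component
        comp_erp = U.T @ erp
        for k in range(U.shape[1]):
            peak = comp_erp[k, np.argmax(np.abs(comp_erp[k]))]
            if peak < 0:
                U[:, k] = -U[:, k]
                comp_erp[k] = -comp_erp[k]
        self.filters_ = U
        self.eigenvalues_ = w[order]
        gram = U.T @ c_total @ U
        self.patterns_ = c_total @ U @ linalg.inv(gram)
        self.evoked_ = comp_erp
        return self

    def transform(self, X):
        """Project epochs onto the xDAWN components: Z = U^T X."""
        X = np.asarray(X)
        if X.shape[-2] != self.filters_.shape[0]:
            raise ValueError("channel count mismatch")
        return np.einsum("ck,nct->nkt", self.filters_, X)


class SuperEpochBuilder(BaseEstimator, TransformerMixin):
    """Stack epoch components with the filtered average target response.

    The evoked response E_Z (mean of spatially filtered calibration target
    epochs) is concatenated below the first ``n_epoch_components`` components
    of every epoch, so each super epoch preserves the template:
    rows = [Z_k,1..3, E_Z,1..4] by default (7 x Nt).
    """

    def __init__(self, n_epoch_components: int = 3, n_evoked_components: int = 4):
        self.n_epoch_components = n_epoch_components
        self.n_evoked_components = n_evoked_components

    def fit(self, Z, y):
        """``Z``: filtered calibration epochs (n, K, Nt); ``y``: labels."""
        Z = np.asarray(Z)
        y = np.asarray(y)
        if not (y == 1).any():
            raise ValueError("calibration set contains no target epochs")
        if Z.shape[1] < max(self.n_epoch_components, self.n_evoked_components):
            raise ValueError("not enough components for the requested super epoch")
        self.evoked_ = Z[y == 1].mean(axis=0)[: self.n_evoked_components]
        return self

    def transform(self, Z):
        Z = np.asarray(Z)
        n = Z.shape[0]
        ev = np.broadcast_to(self.evoked_, (n,) + self.evoked_.shape)
        return np.concatenate([Z[:, : self.n_epoch_components], ev], axis=1)


class RiemannianAlignment(BaseEstimator, TransformerMixin):
    """Align a participant's epochs using the calibration Riemannian mean.

    Ledoit-Wolf covariances of the calibration (super) epochs are averaged
    under the affine-invariant metric; every epoch is then transported with
    that mean.  ``mode="whiten"`` (default) multiplies by R^{-1/2}, which
    maps the calibration covariance cloud to one with identity Riemannian
    mean — the common feature space across participants.  ``mode="literal"``
    multiplies by R itself.
    """

    def __init__(self, mode: str = "whiten", tol: float = 1e-9, max_iter: int = 100):
        self.mode = mode
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X)
        if len(X) == 0:
            raise ValueError("empty calibration set")
        if self.mode not in ("whiten", "literal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        covs = lw_covariances(X)
        R = riemannian_mean(covs, tol=self.tol, max_iter=self.max_iter)
        w = np.linalg.eigvalsh(R)
        if w.min() <= 0:
            raise ValueError("Riemannian mean is not positive definite")
        self.mean_ = R
        self.transport_ = invsqrtm_spd(R) if self.mode == "whiten" else R
        return self

    def transform(self, X):
        return np.einsum("rc,nct->nrt", self.transport_, np.asarray(X))

    def transform_covariances(self, covs: np.ndarray) -> np.ndarray:
        """Congruence action of the transport on covariance matrices.

        T C T^T for each C; in whiten mode the Riemannian mean of the
        calibration covariances maps exactly to the identity (affine
        invariance of the metric).
        """
        T = self.transport_
        return T @ np.asarray(covs) @ T.T


class CompletePreprocessor(BaseEstimator, TransformerMixin):
    """Full participant-specific chain: xDAWN -> super epochs -> alignment.

    Fit on calibration epochs only (standardized, band-passed, BP space);
    ``transform`` maps any epochs of the same participant (or, in the
    combined scheme, of pooled participants) to aligned super epochs.
    ``drop_leading_components`` removes the first k xDAWN components before
    the super-epoch stage (manual QC override for degenerate components).
    """

    def __init__(
        self,
        n_components: int = 4,
        n_epoch_components: int = 3,
        mode: str = "whiten",
        drop_leading_components: int = 0,
    ):
        self.n_components = n_components
        self.n_epoch_components = n_epoch_components
        self.mode = mode
        self.drop_leading_components = drop_leading_components

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        k_extra = self.drop_leading_components
        self.xdawn_ = Xdawn(n_components=self.n_components + k_extra).fit(X, y)
        Z = self.xdawn_.transform(X)[:, k_extra:]
        self.super_ = SuperEpochBuilder(
            n_epoch_components=self.n_epoch_components,
            n_evoked_components=self.n_components,
        ).fit(Z, y)
        S = self.super_.transform(Z)
        self.alignment_ = RiemannianAlignment(mode=self.mode).fit(S)
        return self

    def transform_components(self, X):
        """xDAWN components only (the AP measurement space)."""
        return self.xdawn_.transform(np.asarray(X))[:, self.drop_leading_components :]

    def transform(self, X):
        Z = self.transform_components(X)
        return self.alignment_.transform(self.super_.transform(Z))

    def transform_epochset(self, epochs: EpochSet, space: str = "SUPER") -> EpochSet:
        if space == "AP":
            return epochs.with_data(self.transform_components(epochs.data), "AP")
        return epochs.with_data(self.transform(epochs.data), "SUPER")
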