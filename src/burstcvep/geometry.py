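"""Symmetric-positive-definite matrix geometry (affine-invariant metric).

Ledoit-Wolf covariance estimation for short epochs, matrix functions via
(batched) eigendecomposition, the AIRM (Frechet) mean by fixed-point
iteration, and tangent-space vectorization used by the TS-LDA decoder and
the alignment transform.
"""

from __future__ import annotations

import numpy as np
from sklearn.covariance import LedoitWolf

__all__ = [
    "lw_covariance",
    "lw_covariances",
    "sqrtm_spd",
    "invsqrtm_spd",
    "logm_spd",
    "expm_sym",
    "airm_distance",
    "riemannian_mean",
    "tangent_vectors",
    "untangent",
]


def lw_covariance(epoch: np.ndarray, return_shrinkage: bool = False):
    """Ledoit-Wolf shrinkage covariance of one epoch (rows x samples)."""
    lw = LedoitWolf(assume_centered=False).fit(np.asarray(epoch).T)
    if return_shrinkage:
        return lw.covariance_, float(lw.shrinkage_)
    return lw.covariance_


def lw_covariances(epochs: np.ndarray, return_shrinkage: bool = False):
    """Ledoit-Wolf covariance per epoch, vectorized across epochs.

    ``epochs``: (n, rows, samples).  Returns (n, rows, rows) SPD matrices;
    the shrinkage intensity follows the Ledoit-Wolf closed form (identical
    to fitting each epoch separately, cross-checked in the test suite).
    """
    E = np.asarray(epochs, dtype=np.float64)
    n, d, T = E.shape
    Xc = E - E.mean(axis=2, keepdims=True)          # center per row
    Xc = Xc.transpose(0, 2, 1)                      # (n, T, d)
    S = np.einsum("ntd,nte->nde", Xc, Xc) / T
    X2 = Xc ** 2
    emp_trace = X2.sum(axis=1) / T                  # (n, d)
    mu = emp_trace.sum(axis=1) / d                  # (n,)
    beta_ = np.einsum("ntd,nte->n", X2, X2)
    delta_ = np.einsum("nde,nde->n", S, S) * T ** 2
    delta_ = delta_ / T ** 2
    beta = (beta_ / T - delta_) / (d * T)
    delta = (delta_ - 2.0 * mu * emp_trace.sum(axis=1) + d * mu ** 2) / d
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(delta > 0, np.clip(beta, 0, None), 0.0)
        shrink = np.where(delta > 0, np.minimum(shrink / np.where(delta > 0, delta, 1.0), 1.0), 1.0)
    covs = (1.0 - shrink)[:, None, None] * S
    covs[:, np.arange(d), np.arange(d)] += (shrink * mu)[:, None]
    if return_shrinkage:
        return covs, shrink
    return covs


def _eig_fun(C: np.ndarray, fun) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    return np.einsum("...ij,...j,...kj->...ik", V, fun(w), V)


def sqrtm_spd(C: np.ndarray) -> np.ndarray:
    return _eig_fun(C, np.sqrt)


def invsqrtm_spd(C: np.ndarray) -> np.ndarray:
    return _eig_fun(C, lambda w: 1.0 / np.sqrt(w))


def logm_spd(C: np.ndarray) -> np.ndarray:
    return _eig_fun(C, np.log)


def expm_sym(S: np.ndarray) -> np.ndarray:
    return _eig_fun(S, np.exp)


def airm_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant Riemannian distance ||log(A^-1/2 B A^-1/2)||_F."""
    iA = invsqrtm_spd(A)
    return float(np.linalg.norm(logm_spd(iA @ B @ iA)))


def riemannian_mean(
    mats: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> np.ndarray:
    """AIRM Frechet mean of a stack of SPD matrices.

    Fixed-point iteration M <- M^1/2 exp(mean_i log(M^-1/2 C_i M^-1/2)) M^1/2
    initialised at the arithmetic mean; raises if the Riemannian gradient
    norm has not reached ``tol`` within ``max_iter`` iterations.
    """
    mats = np.asarray(mats)
    if mats.ndim != 3:
        raise ValueError("expected a stack of SPD matrices")
    M = mats.mean(axis=0)
    for _ in range(max_iter):
        iM = invsqrtm_spd(M)
        G = logm_spd(iM @ mats @ iM).mean(axis=0)
        gnorm = np.linalg.norm(G)
        sM = sqrtm_spd(M)
        M = sM @ expm_sym(G) @ sM
        M = (M + M.T) / 2
        if gnorm <= tol:
            return M
    raise RuntimeError(f"Riemannian mean did not converge in {max_iter} iterations")


def _triu_weights(d: int):
    rows, cols = np.triu_indices(d)
    w = np.where(rows == cols, 1.0, np.sqrt(2.0))
    return rows, cols, w


def tangent_vectors(covs: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Project SPD matrices to the tangent space at ``ref``.

    v = upper-tri( log(ref^-1/2 C ref^-1/2) ) with sqrt(2) off-diagonal
    weights, giving d(d+1)/2 coordinates preserving the AIRM inner product.
    """
    covs = np.asarray(covs)
    single = covs.ndim == 2
    if single:
        covs = covs[None]
    iR = invsqrtm_spd(ref)
    S = logm_spd(iR @ covs @ iR)
    rows, cols, w = _triu_weights(covs.shape[-1])
    out = S[:, rows, cols] * w
    return out[0] if single else out


def untangent(vecs: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Inverse of :func:`tangent_vectors` (exponential map at ``ref``)."""
    vecs = np.asarray(vecs)
    single = vecs.ndim == 1
    if single:
        vecs = vecs[None]
    d = int((np.sqrt(8 * vecs.shape[-1] + 1) - 1) / 2)
    rows, cols, w = _triu_weights(d)
    sR = sqrtm_spd(ref)
    S = np.zeros((len(vecs), d, d))
    S[:, rows, cols] = vecs / w
    S = S + np.swapaxes(S, -1, -2)
    S[:, np.arange(d), np.arange(d)] /= 2.0
    out = sR @ expm_sym(S) @ sR
    return out[0] if single else out
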