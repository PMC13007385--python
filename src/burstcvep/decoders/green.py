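"""GREEN: Gabor-Riemannian network for epoch classification.

A learnable Gabor wavelet filterbank (22 bands on a 0-4.4 octave grid)
decomposes each epoch; per band, the channel covariance of the complex
coefficients' real representation is passed through one SPD block — a
shrinkage layer (convex combination with a scaled identity), a BiMap layer
(orthonormal projection to 4 channels on the Stiefel manifold) and a ReEig
layer (eigenvalue floor) — then matrix-log'd and vectorized to the tangent
space at the identity.  The concatenated 22 x 10 coordinates feed a small
fully connected head (20 -> 10 -> 2) with dropout.

The SPD block and head always train by gradient descent; with
``learn_wavelets=True`` the wavelet centers/widths join the graph (kernels
are rebuilt from their parameters at every step).
"""

from __future__ import annotations

import itertools

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .. import nn
from ..wavelets import WaveletFamily, gabor_coefficients

__all__ = ["SpdBlock", "GreenClassifier", "gabor_covariances", "green_hyperparameter_grid"]


def gabor_covariances(
    X: np.ndarray, family: WaveletFamily, fs: float, shrinkage: float = 0.0
) -> np.ndarray:
    """Per-wavelet channel covariances: (n, n_wavelets, c, c).

    C_j = Re(Y_j Y_j^H) / T for the complex Gabor coefficients Y_j of each
    epoch; optional fixed shrinkage (1-a) C + a tr(C)/d I keeps them SPD.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = gabor_coefficients(X, family, fs)  # (n, c, n_wav, T)
    Yr, Yi = Y.real, Y.imag
    C = (
        np.einsum("ncwt,ndwt->nwcd", Yr, Yr)
        + np.einsum("ncwt,ndwt->nwcd", Yi, Yi)
    ) / X.shape[-1]
    if shrinkage > 0:
        d = C.shape[-1]
        tr = np.trace(C, axis1=-2, axis2=-1) / d
        C = (1 - shrinkage) * C
        C[..., np.arange(d), np.arange(d)] += shrinkage * tr[..., None]
    return C


class SpdBlock:
    """Shrinkage -> BiMap -> ReEig on stacks of SPD matrices.

    shrinkage: C' = (1-a) C + a tr(C)/d I with a = sigmoid(rho) in (0, 1);
    bimap: W^T C' W with W (d, k) kept column-orthonormal by QR retraction
    after each optimizer step; reeig: eigenvalues floored at ``eps``.
    """

    def __init__(self, d_in: int, d_out: int = 4, alpha0: float = 0.05,
                 eps: float = 1e-4, rng=None):
        rng = np.random.default_rng(0) if rng is None else rng
        self.rho = nn.Tensor(np.log(alpha0 / (1 - alpha0)), requires_grad=True)
        Q, _ = np.linalg.qr(rng.standard_normal((d_in, d_out)))
        self.W = nn.Tensor(Q, requires_grad=True)
        self.eps = eps
        self.d_in = d_in
        self.d_out = d_out

    def __call__(self, C: nn.Tensor) -> nn.Tensor:
        d = self.d_in
        alpha = nn.sigmoid(self.rho)
        tr = nn.trace_last2(C) * (1.0 / d)  # batch-shaped mean eigenvalue
        eye = nn.Tensor(np.eye(d))
        shrunk = C * (1.0 - alpha) + eye * tr.reshape(*tr.shape, 1, 1) * alpha
        B = nn.matmul(nn.matmul(self.W.swap_last2(), shrunk), self.W)
        return nn.sym_reeig(B, self.eps)

    def retract(self) -> None:
        """Project W back to the Stiefel manifold (QR orthonormalization)."""
        Q, R = np.linalg.qr(self.W.data)
        self.W.data = Q * np.sign(np.diag(R))

    def params(self):
        return [self.rho, self.W]


def green_hyperparameter_grid() -> list[dict]:
    """The published search grid: wavelet count 6-30 (step 2), dropout
    0.4-0.8 (step 0.1), max octave 3.6-5.0 (step 0.2) — 13 x 5 x 8 = 520
    combinations for 5-fold cross-validation."""
    n_wavelets = list(range(6, 31, 2))
    dropouts = [round(0.4 + 0.1 * i, 1) for i in range(5)]
    max_octaves = [round(3.6 + 0.2 * i, 1) for i in range(8)]
    return [
        {"n_wavelets": n, "dropout": p, "max_octave": o}
        for n, p, o in itertools.product(n_wavelets, dropouts, max_octaves)
    ]


class GreenClassifier(BaseEstimator, ClassifierMixin):
    """GREEN with the fit/predict_proba contract.

    With fixed wavelets the per-band covariances are computed once and
    cached, so each training step only runs the SPD block and the head.
    """

    def __init__(
        self,
        n_wavelets: int = 22,
        max_octave: float = 4.4,
        spd_channels: int = 4,
        hidden=(20, 10),
        dropout: float = 0.4,
        lr: float = 3e-3,
        n_epochs: int = 20,
        batch_size: int = 256,
        val_fraction: float = 0.1,
        patience: int = 5,
        learn_wavelets: bool = False,
        fs: float = 500.0,
        seed: int = 0,
    ):
        self.n_wavelets = n_wavelets
        self.max_octave = max_octave
        self.spd_channels = spd_channels
        self.hidden = hidden
        self.dropout = dropout
        self.lr = lr
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.patience = patience
        self.learn_wavelets = learn_wavelets
        self.fs = fs
        self.seed = seed

    # -- construction ------------------------------------------------------
    def _build(self, n_ch: int, rng):
        self.family_ = WaveletFamily(
            n_wavelets=self.n_wavelets, max_octave=self.max_octave,
            learnable=self.learn_wavelets,
        )
        self._oct = nn.Tensor(self.family_.center_octaves.copy(),
                              requires_grad=self.learn_wavelets)
        self._logfwhm = nn.Tensor(np.log(self.family_.fwhm),
                                  requires_grad=self.learn_wavelets)
        self.spd_ = SpdBlock(n_ch, self.spd_channels, rng=rng)
        k = self.spd_channels
        n_feat = self.n_wavelets * (k * (k + 1) // 2)
        h1, h2 = self.hidden
        self._d1 = nn.Linear(n_feat, h1, rng)
        self._d2 = nn.Linear(h1, h2, rng)
        self._d3 = nn.Linear(h2, 2, rng)

    def _params(self):
        p = self.spd_.params() + self._d1.params() + self._d2.params() + self._d3.params()
        if self.learn_wavelets:
            p = [self._oct, self._logfwhm] + p
        return p

    # -- wavelet covariances in-graph (learnable path) ---------------------
    def _cov_graph(self, X: np.ndarray) -> nn.Tensor:
        """Per-wavelet covariances with gradients w.r.t. octave/width."""
        n, c, T = X.shape
        covs = []
        # build each kernel from its parameters, convolve via matmul with
        # an unfolded (Toeplitz) view of the input
        for j in range(self.n_wavelets):
            oct_j = _index(self._oct, j)
            fwhm_j = _index(self._logfwhm, j).exp()
            f_j = (oct_j * np.log(2.0)).exp()
            sigma = fwhm_j * (1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0))))
            half = min((T - 1) // 2, int(np.ceil(3.0 * np.exp(self._logfwhm.data[j])
                        * 0.42466 * self.fs)))
            t = nn.Tensor(np.arange(-half, half + 1) / self.fs)
            env = ((t * t) * (sigma ** -2.0) * -0.5).exp()
            phase = t * f_j * (2.0 * np.pi)
            kr = env * _cos(phase)
            ki = env * _sin(phase)
            norm = ((kr * kr).sum() + (ki * ki).sum()) ** -0.5
            kr, ki = kr * norm, ki * norm
            U = _unfold(X, 2 * half + 1)  # (n, c, T, m) constant
            Ut = nn.Tensor(U)
            yr = nn.matmul(Ut, kr.reshape(-1, 1)).reshape(n, c, T)
            yi = nn.matmul(Ut, ki.reshape(-1, 1)).reshape(n, c, T)
            C = (nn.matmul(yr, yr.swap_last2()) + nn.matmul(yi, yi.swap_last2())) * (1.0 / T)
            covs.append(C.reshape(n, 1, c, c))
        return nn.concat(covs, axis=1)

    def _forward_from_cov(self, C: nn.Tensor, training: bool, rng) -> nn.Tensor:
        n = C.shape[0]
        S = self.spd_(C)
        V = nn.triu_vec(nn.sym_logm(S))
        h = V.reshape(n, -1)
        h = nn.dropout(h, self.dropout, rng, training)
        h = nn.leaky_relu(self._d1(h), 0.01)
        h = nn.dropout(h, self.dropout, rng, training)
        h = nn.leaky_relu(self._d2(h), 0.01)
        return self._d3(h)

    def _logits(self, X: np.ndarray, training: bool, rng,
                cached: np.ndarray | None = None) -> nn.Tensor:
        if self.learn_wavelets:
            C = self._cov_graph(X)
        else:
            data = cached if cached is not None else gabor_covariances(
                X, self.family_, self.fs)
            C = nn.Tensor(data)
        return self._forward_from_cov(C, training, rng)

    # -- training ----------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        rng = np.random.default_rng(self.seed)
        self._build(X.shape[1], rng)
        self._train(X, y, rng, self.n_epochs)
        self.classes_ = np.array([0, 1])
        return self

    def _train(self, X, y, rng, n_epochs):
        n = len(X)
        cached = None if self.learn_wavelets else gabor_covariances(
            X, self.family_, self.fs)
        n_val = int(round(self.val_fraction * n)) if self.val_fraction else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        opt = nn.Adam(self._params(), lr=self.lr)
        best_val, best_state, bad = np.inf, None, 0
        for _ in range(n_epochs):
            order = rng.permutation(tr_idx)
            for s in range(0, len(order), self.batch_size):
                idx = order[s : s + self.batch_size]
                opt.zero_grad()
                logits = self._logits(
                    X[idx], True, rng,
                    cached[idx] if cached is not None else None)
                loss = nn.softmax_cross_entropy(logits, y[idx])
                loss.backward()
                opt.step()
                self.spd_.retract()
                if self.learn_wavelets:
                    np.clip(self._oct.data, 0.0, self.max_octave, out=self._oct.data)
                    self.family_.center_octaves = self._oct.data.copy()
                    self.family_.fwhm = np.exp(self._logfwhm.data)
            if n_val:
                logits = self._logits(
                    X[val_idx], False, rng,
                    cached[val_idx] if cached is not None else None)
                vl = nn.softmax_cross_entropy(logits, y[val_idx]).data
                if vl < best_val - 1e-5:
                    best_val, bad = vl, 0
                    best_state = [p.data.copy() for p in self._params()]
                else:
                    bad += 1
                    if bad >= self.patience:
                        break
        if best_state is not None:
            for p, s in zip(self._params(), best_state):
                p.data = s
            self.spd_.retract()
        return self

    def finetune(self, X, y, n_epochs: int | None = None):
        """Continue training on new data; 0 epochs is a no-op."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        n_epochs = self.n_epochs if n_epochs is None else n_epochs
        if n_epochs == 0:
            return self
        rng = np.random.default_rng(self.seed + 1)
        return self._train(X, y, rng, n_epochs)

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        rng = np.random.default_rng(0)  # unused: dropout off at inference
        out = []
        for s in range(0, len(X), 2048):
            logits = self._logits(X[s : s + 2048], False, rng)
            out.append(nn.softmax_probs(logits.data))
        return np.concatenate(out)

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)


# -- helpers for the learnable-wavelet graph ---------------------------------

def _index(t: nn.Tensor, j: int) -> nn.Tensor:
    """Differentiable scalar view t[j]."""
    mask = np.zeros(t.shape)
    mask[j] = 1.0
    return (t * nn.Tensor(mask)).sum()


def _cos(x: nn.Tensor) -> nn.Tensor:
    out = nn.Tensor(np.cos(x.data), x.requires_grad, (x,))

    def back():
        x._accum(-out.grad * np.sin(x.data))

    out._backward = back
    return out


def _sin(x: nn.Tensor) -> nn.Tensor:
    out = nn.Tensor(np.sin(x.data), x.requires_grad, (x,))

    def back():
        x._accum(out.grad * np.cos(x.data))

    out._backward = back
    return out


def _unfold(X: np.ndarray, m: int) -> np.ndarray:
    """'same'-mode sliding windows: (n, c, T, m) with zero padding."""
    n, c, T = X.shape
    pad = m // 2
    Xp = np.pad(X, ((0, 0), (0, 0), (pad, m - 1 - pad)))
    return np.lib.stride_tricks.sliding_window_view(Xp, m, axis=2)[..., ::-1]
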