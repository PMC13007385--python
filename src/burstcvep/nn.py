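"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the CNN and GREEN decoders need: broadcasted
arithmetic, (batched) matmul, dilated 2-D convolution, max pooling, batch
normalization, dropout, leaky ReLU, softmax cross-entropy, and spectral
functions of symmetric matrices (matrix log, eigenvalue flooring) with the
Daleckii-Krein / Loewner-matrix backward rule.  An Adam optimizer and tiny
layer classes sit on top.

Gradients are validated against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "matmul", "conv2d", "maxpool2d", "leaky_relu", "sigmoid",
    "dropout", "softmax_cross_entropy", "sym_logm", "sym_reeig", "triu_vec",
    "trace_last2", "concat", "Adam", "Linear", "BatchNorm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # numpy defers to Tensor in mixed expressions

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- graph machinery ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    def _accum(self, grad):
        if self.requires_grad:
            self.grad = grad if self.grad is None else self.grad + grad

    # -- elementwise arithmetic --------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def back():
            self._accum(_unbroadcast(out.grad, self.shape))
            other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def back():
            self._accum(_unbroadcast(out.grad * other.data, self.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def back():
            self._accum(out.grad * p * self.data ** (p - 1.0))

        out._backward = back
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def back():
            self._accum(out.grad.reshape(self.shape))

        out._backward = back
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def back():
            self._accum(out.grad.transpose(inv))

        out._backward = back
        return out

    def swap_last2(self):
        ax = list(range(self.data.ndim))
        ax[-1], ax[-2] = ax[-2], ax[-1]
        return self.transpose(*ax)

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def back():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def back():
            self._accum(out.grad * out.data)

        out._backward = back
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def back():
            self._accum(out.grad / self.data)

        out._backward = back
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, a.requires_grad or b.requires_grad, (a, b))

    def back():
        ga = out.grad @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ out.grad
        a._accum(_unbroadcast(ga, a.shape))
        b._accum(_unbroadcast(gb, b.shape))

    out._backward = back
    return out


def leaky_relu(x: Tensor, alpha: float = 0.01) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, alpha * x.data), x.requires_grad, (x,))

    def back():
        x._accum(out.grad * np.where(mask, 1.0, alpha))

    out._backward = back
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, x.requires_grad, (x,))

    def back():
        x._accum(out.grad * s * (1.0 - s))

    out._backward = back
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p == 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]

    def back():
        splits = np.cumsum(sizes)[:-1]
        for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
            t._accum(g)

    out._backward = back
    return out


# -- convolution / pooling ---------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           dilation=(1, 1), padding="same") -> Tensor:
    """Stride-1 dilated 2-D convolution (cross-correlation).

    x: (N, C_in, H, W); w: (C_out, C_in, kh, kw); padding 'same' or 'valid'.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    dh, dw = dilation
    co, ci, kh, kw = w.shape
    eh, ew = (kh - 1) * dh + 1, (kw - 1) * dw + 1  # effective kernel extent
    if padding == "same":
        ph, pw = eh - 1, ew - 1
        pt, pl = ph // 2, pw // 2
        xp = np.pad(x.data, ((0, 0), (0, 0), (pt, ph - pt), (pl, pw - pl)))
    elif padding == "valid":
        pt = pl = 0
        xp = x.data
    else:
        raise ValueError("padding must be 'same' or 'valid'")
    n, _, hp, wp = xp.shape
    ho, wo = hp - eh + 1, wp - ew + 1
    if ho <= 0 or wo <= 0:
        raise ValueError("input smaller than the (dilated) kernel")
    out_data = np.zeros((n, co, ho, wo))
    for p in range(kh):
        for q in range(kw):
            win = xp[:, :, p * dh : p * dh + ho, q * dw : q * dw + wo]
            out_data += np.einsum("oc,nchw->nohw", w.data[:, :, p, q], win)
    if b is not None:
        out_data += b.data.reshape(1, co, 1, 1)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, any(t.requires_grad for t in prev), prev)

    def back():
        g = out.grad
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for p in range(kh):
            for q in range(kw):
                win = xp[:, :, p * dh : p * dh + ho, q * dw : q * dw + wo]
                gw[:, :, p, q] = np.einsum("nohw,nchw->oc", g, win)
                gxp[:, :, p * dh : p * dh + ho, q * dw : q * dw + wo] += np.einsum(
                    "oc,nohw->nchw", w.data[:, :, p, q], g)
        if padding == "same":
            gx = gxp[:, :, pt : pt + x.shape[2], pl : pl + x.shape[3]]
        else:
            gx = gxp
        x._accum(gx)
        w._accum(gw)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = back
    return out


def maxpool2d(x: Tensor, pool=(1, 2)) -> Tensor:
    """Non-overlapping max pooling; trailing remainder is cropped."""
    x = _as_tensor(x)
    ph, pw = pool
    n, c, h, w = x.shape
    ho, wo = h // ph, w // pw
    xc = x.data[:, :, : ho * ph, : wo * pw]
    xr = xc.reshape(n, c, ho, ph, wo, pw).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, ho, wo, ph * pw)
    idx = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))

    def back():
        gr = np.zeros((n, c, ho, wo, ph * pw))
        np.put_along_axis(gr, idx[..., None], out.grad[..., None], axis=-1)
        gr = gr.reshape(n, c, ho, wo, ph, pw).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros_like(x.data)
        gx[:, :, : ho * ph, : wo * pw] = gr.reshape(n, c, ho * ph, wo * pw)
        x._accum(gx)

    out._backward = back
    return out


def softmax_cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    logits = _as_tensor(logits)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    out = Tensor(loss, logits.requires_grad, (logits,))

    def back():
        g = p.copy()
        g[np.arange(n), y] -= 1.0
        logits._accum(out.grad * g / n)

    out._backward = back
    return out


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


# -- spectral ops on symmetric matrices --------------------------------------

def _sym_fn(x: Tensor, fn, dfn) -> Tensor:
    """F = U f(L) U^T for symmetric x (..., d, d).

    Backward uses the Daleckii-Krein theorem: dF = U (K o (U^T dX U)) U^T
    with the Loewner matrix K_ij = (f(li) - f(lj)) / (li - lj), f'(li) on
    the diagonal / for coincident eigenvalues.
    """
    x = _as_tensor(x)
    xs = (x.data + np.swapaxes(x.data, -1, -2)) / 2
    w, V = np.linalg.eigh(xs)
    fw = fn(w)
    out_data = np.einsum("...ij,...j,...kj->...ik", V, fw, V)
    out = Tensor(out_data, x.requires_grad, (x,))

    def back():
        g = (out.grad + np.swapaxes(out.grad, -1, -2)) / 2
        dw = w[..., :, None] - w[..., None, :]
        df = fw[..., :, None] - fw[..., None, :]
        near = np.abs(dw) < 1e-12
        K = np.where(near, 0.0, df / np.where(near, 1.0, dw))
        deriv = dfn(w)
        K = K + near * (deriv[..., :, None] + deriv[..., None, :]) / 2
        M = np.einsum("...ji,...jk,...kl->...il", V, g, V)
        gx = np.einsum("...ij,...jk,...lk->...il", V, K * M, V)
        x._accum((gx + np.swapaxes(gx, -1, -2)) / 2)

    out._backward = back
    return out


def sym_logm(x: Tensor) -> Tensor:
    """Matrix logarithm of SPD matrices (batched)."""
    return _sym_fn(x, np.log, lambda w: 1.0 / w)


def sym_reeig(x: Tensor, eps: float = 1e-4) -> Tensor:
    """ReEig: floor eigenvalues at ``eps`` (rectified eigenvalue layer)."""
    return _sym_fn(x, lambda w: np.maximum(w, eps),
                   lambda w: (w > eps).astype(float))


def trace_last2(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    d = x.shape[-1]
    out = Tensor(np.trace(x.data, axis1=-2, axis2=-1), x.requires_grad, (x,))

    def back():
        g = out.grad[..., None, None] * np.eye(d)
        x._accum(g)

    out._backward = back
    return out


def triu_vec(x: Tensor, sqrt2_offdiag: bool = True) -> Tensor:
    """Upper-triangle vectorization of (..., d, d) -> (..., d(d+1)/2)."""
    x = _as_tensor(x)
    d = x.shape[-1]
    rows, cols = np.triu_indices(d)
    wvec = np.where(rows == cols, 1.0, np.sqrt(2.0)) if sqrt2_offdiag else np.ones(len(rows))
    out = Tensor(x.data[..., rows, cols] * wvec, x.requires_grad, (x,))

    def back():
        gx = np.zeros_like(x.data)
        gx[..., rows, cols] = out.grad * wvec
        x._accum(gx)

    out._backward = back
    return out


# -- layers and optimizer -----------------------------------------------------

class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-lim, lim, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.W) + self.b

    def params(self):
        return [self.W, self.b]


class BatchNorm:
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = (0,) + tuple(range(2, x.data.ndim))
        shape = (1, -1) + (1,) * (x.data.ndim - 2)
        if training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(*shape) + self.beta.reshape(*shape)

    def params(self):
        return [self.gamma, self.beta]


class Adam:
    """Adam optimizer (Kingma & Ba defaults except the learning rate)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
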