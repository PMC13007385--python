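"""EEG2Code-style convolutional flash classifier.

Three convolutional blocks — a spatial convolution over the full channel
axis (kernel (Nc, 1)) with batch normalization, then a temporal (1, 32) and
a spatio-temporal (5, 5) convolution with dilation rates (1, 2) and (2, 2)
and leaky-ReLU activations — each followed by max pooling along time and
dropout 0.5; a 256-unit dense layer (leaky ReLU) and a 2-unit softmax head.
Trained with Adam at learning rate 0.001.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .. import nn

__all__ = ["CNNClassifier"]


class CNNClassifier(BaseEstimator, ClassifierMixin):
    """Epoch-level CNN with the fit/predict_proba contract.

    ``n_filters`` sets the per-block filter counts; the printed architecture
    leaves them open, and (16, 8, 4) keeps the parameter count in the tens
    of thousands.  Dropout is disabled at inference, so predictions are
    deterministic after fit.
    """

    def __init__(
        self,
        n_filters=(16, 8, 4),
        dense_units: int = 256,
        lr: float = 1e-3,
        n_epochs: int = 20,
        batch_size: int = 256,
        dropout: float = 0.5,
        leaky_alpha: float = 0.01,
        val_fraction: float = 0.1,
        patience: int = 5,
        seed: int = 0,
    ):
        self.n_filters = n_filters
        self.dense_units = dense_units
        self.lr = lr
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.dropout = dropout
        self.leaky_alpha = leaky_alpha
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed

    # -- architecture ------------------------------------------------------
    def _build(self, n_channels: int, n_samples: int, rng):
        f1, f2, f3 = self.n_filters
        glorot = lambda shape: rng.uniform(
            -np.sqrt(6.0 / (np.prod(shape[1:]) + shape[0])),
            np.sqrt(6.0 / (np.prod(shape[1:]) + shape[0])),
            shape,
        )
        self._w1 = nn.Tensor(glorot((f1, 1, n_channels, 1)), requires_grad=True)
        self._b1 = nn.Tensor(np.zeros(f1), requires_grad=True)
        self._bn = nn.BatchNorm(f1)
        self._w2 = nn.Tensor(glorot((f2, f1, 1, 32)), requires_grad=True)
        self._b2 = nn.Tensor(np.zeros(f2), requires_grad=True)
        self._w3 = nn.Tensor(glorot((f3, f2, 5, 5)), requires_grad=True)
        self._b3 = nn.Tensor(np.zeros(f3), requires_grad=True)
        n_flat = f3 * (n_samples // 8)  # three time-poolings of 2
        self._d1 = nn.Linear(n_flat, self.dense_units, rng)
        self._d2 = nn.Linear(self.dense_units, 2, rng)

    def _params(self):
        return (
            [self._w1, self._b1] + self._bn.params()
            + [self._w2, self._b2, self._w3, self._b3]
            + self._d1.params() + self._d2.params()
        )

    def _forward(self, X: np.ndarray, training: bool, rng) -> nn.Tensor:
        x = nn.Tensor(X[:, None])  # (n, 1, Nc, Nt)
        a = self.leaky_alpha
        h = nn.conv2d(x, self._w1, self._b1, padding="valid")
        h = self._bn(h, training)
        h = nn.maxpool2d(h, (1, 2))
        h = nn.dropout(h, self.dropout, rng, training)
        h = nn.conv2d(h, self._w2, self._b2, dilation=(1, 2), padding="same")
        h = nn.maxpool2d(nn.leaky_relu(h, a), (1, 2))
        h = nn.dropout(h, self.dropout, rng, training)
        h = nn.conv2d(h, self._w3, self._b3, dilation=(2, 2), padding="same")
        h = nn.maxpool2d(nn.leaky_relu(h, a), (1, 2))
        h = nn.dropout(h, self.dropout, rng, training)
        h = h.reshape(len(X), -1)
        h = nn.leaky_relu(self._d1(h), a)
        return self._d2(h)

    # -- training ----------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        n, n_ch, n_t = X.shape
        if n_t < 32:
            raise ValueError("need at least 32 samples per epoch")
        rng = np.random.default_rng(self.seed)
        self._build(n_ch, n_t, rng)
        self._train(X, y, rng, self.n_epochs, self.lr)
        self.classes_ = np.array([0, 1])
        return self

    def _train(self, X, y, rng, n_epochs, lr):
        n = len(X)
        n_val = int(round(self.val_fraction * n)) if self.val_fraction else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        opt = nn.Adam(self._params(), lr=lr)
        best_val, best_state, bad = np.inf, None, 0
        for _ in range(n_epochs):
            order = rng.permutation(tr_idx)
            for s in range(0, len(order), self.batch_size):
                idx = order[s : s + self.batch_size]
                opt.zero_grad()
                logits = self._forward(X[idx], True, rng)
                loss = nn.softmax_cross_entropy(logits, y[idx])
                loss.backward()
                opt.step()
            if n_val:
                logits = self._forward(X[val_idx], False, rng)
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
        return self

    def finetune(self, X, y, n_epochs: int | None = None):
        """Continue training on new data (pretrain/fine-tune procedure).

        The fine-tuning budget defaults to the within-participant budget
        (same epoch count as ``fit``); 0 epochs leaves the model unchanged.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        n_epochs = self.n_epochs if n_epochs is None else n_epochs
        if n_epochs == 0:
            return self
        rng = np.random.default_rng(self.seed + 1)
        return self._train(X, y, rng, n_epochs, self.lr)

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        out = []
        rng = np.random.default_rng(0)  # unused: dropout off at inference
        for s in range(0, len(X), 2048):
            logits = self._forward(X[s : s + 2048], False, rng)
            out.append(nn.softmax_probs(logits.data))
        return np.concatenate(out)

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)
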