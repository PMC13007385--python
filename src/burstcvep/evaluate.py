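"""Trial-level decoding and evaluation metrics.

The epoch classifier reconstructs a running series of 0/1 flash predictions;
at every epoch the series so far is compared with each code's prefix by
Pearson correlation, and the trial decision is emitted once the last 30
correlation argmaxes agree (dynamic stopping), or at end-of-trial.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import balanced_accuracy_score, f1_score, recall_score

__all__ = [
    "TrialDecodingResult",
    "running_code_correlation",
    "prefix_correlations",
    "dynamic_stop",
    "decode_trial",
    "decode_trial_from_probs",
    "epoch_metrics",
]


def _pearson_prefix(pred: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Pearson r between pred[:t+1] and each code[:t+1], for every t.

    Vectorized over prefixes with cumulative sums; zero-variance prefixes
    (constant predictions or constant code prefix) give r = 0.
    Returns (n_steps, n_codes).
    """
    pred = np.asarray(pred, dtype=float)
    codes = np.asarray(codes, dtype=float)
    n = pred.size
    t = np.arange(1, n + 1)[:, None]
    sp = np.cumsum(pred)[:, None]
    sp2 = np.cumsum(pred ** 2)[:, None]
    sc = np.cumsum(codes, axis=1).T
    sc2 = np.cumsum(codes ** 2, axis=1).T
    spc = np.cumsum(pred[None, :] * codes, axis=1).T
    cov = spc - sp * sc / t
    vp = sp2 - sp ** 2 / t
    vc = sc2 - sc ** 2 / t
    denom = np.sqrt(np.clip(vp * vc, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 1e-12, cov / np.where(denom > 1e-12, denom, 1.0), 0.0)
    return r


def prefix_correlations(pred: np.ndarray, codes_upsampled: np.ndarray) -> np.ndarray:
    """All running correlations at once: (n_steps, n_codes)."""
    codes_upsampled = np.atleast_2d(codes_upsampled)
    if codes_upsampled.shape[1] != len(pred):
        raise ValueError("prediction / code length mismatch")
    return _pearson_prefix(pred, codes_upsampled)


def running_code_correlation(
    pred_bits: np.ndarray, codes_upsampled: np.ndarray, t: int
) -> np.ndarray:
    """Correlation of predictions[0..t] with each code's prefix [0..t]."""
    if t < 2:
        raise ValueError("need at least 3 predictions (t >= 2)")
    pred_bits = np.asarray(pred_bits)
    return prefix_correlations(pred_bits[: t + 1], codes_upsampled[:, : t + 1])[-1]


def dynamic_stop(
    argmax_stream: np.ndarray, window: int = 30, ignore: int | None = None
) -> tuple[int, int]:
    """Earliest epoch where the last ``window`` argmaxes agree.

    Returns (decided_code, stop_epoch); ``stop_epoch`` is the 1-based count
    of epochs consumed.  Without a stable window the decision falls to the
    final argmax at end-of-trial.  Entries equal to ``ignore`` mark epochs
    with no usable vote (e.g. an all-tied correlation vector) and never
    form a stable window.
    """
    s = np.asarray(argmax_stream)
    if s.size == 0:
        raise ValueError("empty argmax stream")
    if window < 1:
        raise ValueError("window must be >= 1")
    for t in range(window - 1, s.size):
        w = s[t - window + 1 : t + 1]
        if (w == w[0]).all() and not (ignore is not None and w[0] == ignore):
            return int(w[0]), t + 1
    return int(s[-1]), s.size


@dataclasses.dataclass
class TrialDecodingResult:
    """Outcome of decoding one trial."""

    trial_id: int
    pred_bits: np.ndarray
    probs: np.ndarray
    correlations: np.ndarray  # (n_epochs, n_codes)
    argmax_codes: np.ndarray
    decided_code: int
    stop_epoch: int
    stopped_early: bool
    true_code: int | None = None

    @property
    def correct(self) -> bool | None:
        if self.true_code is None:
            return None
        return self.decided_code == self.true_code


def decode_trial(
    classifier,
    trial_epochs: np.ndarray,
    codes_at_starts: np.ndarray,
    true_code: int | None = None,
    trial_id: int = 0,
    window: int = 30,
    use_probabilities: bool = False,
) -> TrialDecodingResult:
    """Decode one trial from its ordered epochs.

    ``codes_at_starts``: (n_codes, n_epochs) code bits at the epoch start
    samples.  Hard 0/1 predictions feed the correlation by default (the
    reconstructed bit series); ``use_probabilities`` correlates P(flash)
    instead.  Argmax ties break toward the lowest code index.
    """
    probs = classifier.predict_proba(trial_epochs)[:, 1]
    return decode_trial_from_probs(
        probs, codes_at_starts, true_code=true_code, trial_id=trial_id,
        window=window, use_probabilities=use_probabilities,
    )


def decode_trial_from_probs(
    probs: np.ndarray,
    codes_at_starts: np.ndarray,
    true_code: int | None = None,
    trial_id: int = 0,
    window: int = 30,
    use_probabilities: bool = False,
) -> TrialDecodingResult:
    """Trial decision from per-epoch flash probabilities (in onset order)."""
    probs = np.asarray(probs, dtype=float)
    if len(probs) != codes_at_starts.shape[1]:
        raise ValueError("epoch count does not match code length")
    pred = probs if use_probabilities else (probs >= 0.5).astype(float)
    corr = prefix_correlations(pred, codes_at_starts)
    argmaxes = corr.argmax(axis=1)
    # epochs whose correlation vector carries no information (all entries
    # tied, e.g. a still-constant prediction prefix) cast no vote and
    # cannot satisfy the stability rule
    ties = np.ptp(corr, axis=1) < 1e-12
    votes = np.where(ties, -1, argmaxes)
    decided, stop = dynamic_stop(votes, window=window, ignore=-1)
    if decided == -1:  # never informative: fall back to the final argmax
        decided = int(argmaxes[-1])
    return TrialDecodingResult(
        trial_id=trial_id,
        pred_bits=pred,
        probs=probs,
        correlations=corr,
        argmax_codes=argmaxes,
        decided_code=decided,
        stop_epoch=stop,
        stopped_early=stop < len(argmaxes),
        true_code=true_code,
    )


def epoch_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Balanced accuracy, recall and f1 for the flash class.

    Balanced accuracy is the mean of the two per-class recalls; it is
    reported as nan when the truth contains a single class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("label vectors must be non-empty and equal-length")
    out = {
        "recall": float(recall_score(y_true, y_pred, pos_label=1, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, pos_label=1, zero_division=0)),
    }
    if np.unique(y_true).size < 2:
        out["balanced_accuracy"] = float("nan")
    else:
        out["balanced_accuracy"] = float(balanced_accuracy_score(y_true, y_pred))
    return out
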