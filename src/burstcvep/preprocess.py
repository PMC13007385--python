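"""Temporal filtering, overlapping epoching, standardization and splits.

The "small" preprocessing scheme is: 1-45 Hz linear-phase FIR filter,
overlapping 0.35 s epochs extracted every sample, division by the scalar
standard deviation of the participant's training set.  Epoch labels mark
whether a flash was being presented at the epoch's start sample.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import SimulatedSession

__all__ = [
    "EpochSet",
    "SplitSpec",
    "bandpass_fir",
    "slice_epochs",
    "Standardizer",
    "standardize",
    "undersample",
    "make_split",
]

WINDOW_S = 0.35


@dataclasses.dataclass
class EpochSet:
    """Epochs with flash labels and full provenance indices.

    data : (n_epochs, n_rows, n_samples); rows are channels (BP), xDAWN
    components (AP) or wavelet envelopes (BPWave/APWave), per ``space_tag``.
    ``onset_sample`` is the epoch start sample relative to its trial.
    """

    data: np.ndarray
    labels: np.ndarray
    class_index: np.ndarray
    trial_index: np.ndarray
    run_index: np.ndarray
    participant_id: np.ndarray
    onset_sample: np.ndarray
    fs: float
    space_tag: str = "BP"

    def __post_init__(self) -> None:
        n = len(self.data)
        for f in ("labels", "class_index", "trial_index", "run_index",
                  "participant_id", "onset_sample"):
            arr = np.asarray(getattr(self, f))
            if arr.ndim == 0:
                arr = np.full(n, arr)
            if len(arr) != n:
                raise ValueError(f"{f} length mismatch")
            setattr(self, f, arr)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.data)

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[mask],
            labels=self.labels[mask],
            class_index=self.class_index[mask],
            trial_index=self.trial_index[mask],
            run_index=self.run_index[mask],
            participant_id=self.participant_id[mask],
            onset_sample=self.onset_sample[mask],
            fs=self.fs,
            space_tag=self.space_tag,
        )

    def with_data(self, data: np.ndarray, space_tag: str | None = None) -> "EpochSet":
        """Same metadata, new data array (e.g. after a spatial transform)."""
        if len(data) != len(self):
            raise ValueError("data length mismatch")
        out = dataclasses.replace(self, data=data)
        if space_tag is not None:
            out.space_tag = space_tag
        return out

    @staticmethod
    def concatenate(sets: list["EpochSet"]) -> "EpochSet":
        if not sets:
            raise ValueError("empty list")
        tags = {s.space_tag for s in sets}
        if len(tags) > 1:
            raise ValueError("cannot concatenate epochs from different spaces")
        return EpochSet(
            data=np.concatenate([s.data for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            class_index=np.concatenate([s.class_index for s in sets]),
            trial_index=np.concatenate([s.trial_index for s in sets]),
            run_index=np.concatenate([s.run_index for s in sets]),
            participant_id=np.concatenate([s.participant_id for s in sets]),
            onset_sample=np.concatenate([s.onset_sample for s in sets]),
            fs=sets[0].fs,
            space_tag=sets[0].space_tag,
        )


def design_fir(low: float, high: float, fs: float, transition: float = 1.0) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase bandpass taps."""
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # odd length -> type-I linear phase
    return signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs, window="hamming")


def bandpass_fir(
    eeg: np.ndarray, low: float = 1.0, high: float = 45.0, fs: float = 500.0
) -> np.ndarray:
    """Zero-phase 1-45 Hz FIR filter applied along the last axis.

    Forward-backward application of a linear-phase windowed-sinc filter:
    no phase distortion, and stopband attenuation is doubled (DC and 50 Hz
    mains are suppressed far beyond 40 dB).
    """
    if not 0 < low < high < fs / 2:
        raise ValueError("need 0 < low < high < fs/2")
    taps = design_fir(low, high, fs)
    if eeg.shape[-1] <= 3 * len(taps):
        raise ValueError(
            f"signal ({eeg.shape[-1]} samples) too short for filter length {len(taps)}"
        )
    return signal.filtfilt(taps, 1.0, eeg, axis=-1)


def slice_epochs(
    session: SimulatedSession,
    window: float = WINDOW_S,
    stride_samples: int = 1,
    filtered_eeg: np.ndarray | None = None,
) -> EpochSet:
    """Overlapping epochs from every trial of a session.

    A trial of L samples yields ``L - Nt`` epoch start positions (stride 1),
    with ``Nt = round(window * fs)`` — for 15 trials of 2.2 s per class at
    500 Hz this is 15 * (2.2 - 0.35) * 500 = 13875 epochs per class.  The
    label of an epoch is the upsampled code bit at its start sample
    (sample-and-hold of the 60 Hz frame sequence at fs).
    """
    fs = session.fs
    nt = int(round(window * fs))
    if not np.isclose(nt, window * fs):
        raise ValueError("window * fs must be integral")
    L = session.trial_samples
    if L < nt:
        raise ValueError("trials shorter than the epoch window")
    n_starts = L - nt
    if n_starts == 0:
        warnings.warn("trial length equals window: zero epochs emitted", stacklevel=2)
    starts = np.arange(0, n_starts, stride_samples)

    eeg = filtered_eeg if filtered_eeg is not None else session.eeg
    codes_up = session.code_set.upsample(fs)  # (n_codes, L)

    data, labels, cls, tri, run, onset = [], [], [], [], [], []
    for row in session.schedule:
        s0 = int(row["start_sample"])
        trial = eeg[:, s0 : s0 + L]
        windows = np.lib.stride_tricks.sliding_window_view(trial, nt, axis=1)
        data.append(windows[:, starts].transpose(1, 0, 2))
        code = int(row["code_index"])
        labels.append(codes_up[code, starts])
        cls.append(np.full(len(starts), code))
        tri.append(np.full(len(starts), int(row["trial"])))
        run.append(np.full(len(starts), int(row["run"])))
        onset.append(starts)

    return EpochSet(
        data=np.ascontiguousarray(np.concatenate(data), dtype=np.float64),
        labels=np.concatenate(labels).astype(np.int64),
        class_index=np.concatenate(cls),
        trial_index=np.concatenate(tri),
        run_index=np.concatenate(run),
        participant_id=np.full(len(starts) * len(session.schedule), session.participant_id),
        onset_sample=np.concatenate(onset),
        fs=fs,
        space_tag="BP",
    )


class Standardizer(BaseEstimator, TransformerMixin):
    """Divide by the scalar SD of the participant's training set.

    One standard deviation over all channels and samples of the training
    epochs; after the transform the training set has unit SD.
    """

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.size == 0:
            raise ValueError("cannot fit on an empty training set")
        sd = float(X.std())
        if sd == 0:
            raise ValueError("zero standard deviation (constant training data)")
        self.sd_ = sd
        return self

    def transform(self, X):
        return np.asarray(X) / self.sd_


def standardize(epochs: EpochSet, stats_from: EpochSet) -> EpochSet:
    """Functional wrapper over :class:`Standardizer` for EpochSets."""
    sc = Standardizer().fit(stats_from.data)
    return epochs.with_data(sc.transform(epochs.data))


def undersample(epochs: EpochSet, seed: int = 0) -> EpochSet:
    """Random undersampling of the majority class to a 1:1 balance.

    Training sets only — test sets stay imbalanced to mimic online use.
    """
    labels = epochs.labels
    counts = {c: int((labels == c).sum()) for c in (0, 1)}
    if min(counts.values()) == 0:
        raise ValueError("both classes must be present for undersampling")
    n_keep = min(counts.values())
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(labels), dtype=bool)
    for c in (0, 1):
        idx = np.flatnonzero(labels == c)
        if len(idx) > n_keep:
            idx = rng.choice(idx, size=n_keep, replace=False)
        keep[idx] = True
    return epochs.select(keep)


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Train/test trial assignment for one evaluation.

    ``train_trials`` / ``test_trials`` are sets of (participant_id, trial)
    pairs.  WP trains on the target's first two runs (10 trials, 22 s of
    data); DA adds all 75 trials of one source participant.
    """

    procedure: str
    target_id: int
    source_id: int | None
    train_trials: frozenset
    test_trials: frozenset

    @property
    def calibration_seconds(self) -> float:
        n_target_train = sum(1 for p, _ in self.train_trials if p == self.target_id)
        return n_target_train * 2.2


def make_split(
    procedure: str,
    target_id: int,
    source_id: int | None = None,
    n_runs: int = 15,
    trials_per_run: int = 5,
    calib_runs: int = 2,
) -> SplitSpec:
    """Build the Within-Participant or Domain-Adaptation split.

    WP: target runs 1-2 train, runs 3-15 test.  DA / PRETRAIN_FT: all source
    trials plus target runs 1-2 train; test is target runs 3-15.
    """
    procedure = procedure.upper()
    if procedure not in ("WP", "DA", "PRETRAIN_FT"):
        raise ValueError(f"unknown procedure {procedure!r}")
    n_calib = calib_runs * trials_per_run
    n_total = n_runs * trials_per_run
    target_train = {(target_id, t) for t in range(n_calib)}
    test = {(target_id, t) for t in range(n_calib, n_total)}
    if procedure == "WP":
        if source_id is not None and source_id != target_id:
            raise ValueError("WP takes no distinct source participant")
        train = target_train
        source_id = None
    else:
        if source_id is None:
            raise ValueError(f"{procedure} requires a source participant")
        if source_id == target_id:
            raise ValueError("source must differ from target")
        train = target_train | {(source_id, t) for t in range(n_total)}
    return SplitSpec(
        procedure=procedure,
        target_id=target_id,
        source_id=source_id,
        train_trials=frozenset(train),
        test_trials=frozenset(test),
    )
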