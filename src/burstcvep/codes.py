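"""Aperiodic burst stimulus codes.

A burst code is a binary sequence at the monitor frame rate in which brief
flashes (a few frames each) occur aperiodically at a target rate of ~3 Hz,
with a hard refractory gap between consecutive flash onsets.  A set of codes
drives the simultaneously presented targets; decodability at the trial level
rests on the codes having near-zero pairwise cross-correlation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["BurstCode", "CodeSet", "generate_burst_codes", "pairwise_zero_lag_xcorr"]


@dataclasses.dataclass(frozen=True)
class BurstCode:
    """One binary flash sequence at the stimulus frame rate.

    Parameters
    ----------
    bits : ndarray of {0, 1}, shape (n_frames,)
        Frame-wise stimulus state; a flash sets ``flash_frames`` consecutive
        frames to 1 starting at its onset frame.
    frame_rate : float
        Presentation rate in Hz.
    duration : float
        Sequence duration in seconds.
    onsets : ndarray of float
        Flash onset times in seconds, strictly increasing.
    """

    bits: np.ndarray
    frame_rate: float
    duration: float
    onsets: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must be binary")
        object.__setattr__(self, "bits", bits)
        object.__setattr__(self, "onsets", np.asarray(self.onsets, dtype=float))

    @property
    def n_frames(self) -> int:
        return self.bits.size

    @property
    def onset_frames(self) -> np.ndarray:
        return np.round(self.onsets * self.frame_rate).astype(int)

    def min_onset_gap(self) -> float:
        """Smallest inter-onset interval in seconds (inf for < 2 onsets)."""
        if self.onsets.size < 2:
            return float("inf")
        return float(np.diff(self.onsets).min())

    def upsample(self, fs: float) -> np.ndarray:
        """Sample-and-hold the frame sequence at sampling rate ``fs`` Hz."""
        n_samples = int(round(self.duration * fs))
        frame_of_sample = np.floor(
            np.arange(n_samples) * self.frame_rate / fs
        ).astype(int)
        frame_of_sample = np.clip(frame_of_sample, 0, self.n_frames - 1)
        return self.bits[frame_of_sample]


@dataclasses.dataclass(frozen=True)
class CodeSet:
    """A family of burst codes sharing frame rate and duration.

    ``max_pairwise_xcorr`` is the certificate: the largest absolute zero-lag
    Pearson correlation between the bit sequences of any two distinct codes.
    """

    codes: tuple
    max_pairwise_xcorr: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", tuple(self.codes))
        lengths = {c.n_frames for c in self.codes}
        rates = {c.frame_rate for c in self.codes}
        if len(lengths) > 1 or len(rates) > 1:
            raise ValueError("all codes must share length and frame rate")

    def __len__(self) -> int:
        return len(self.codes)

    def __getitem__(self, i: int) -> BurstCode:
        return self.codes[i]

    @property
    def frame_rate(self) -> float:
        return self.codes[0].frame_rate

    @property
    def duration(self) -> float:
        return self.codes[0].duration

    def bits_matrix(self) -> np.ndarray:
        return np.stack([c.bits for c in self.codes])

    def upsample(self, fs: float) -> np.ndarray:
        """All codes sample-and-held at ``fs``: shape (n_codes, n_samples)."""
        return np.stack([c.upsample(fs) for c in self.codes])


def pairwise_zero_lag_xcorr(bits: np.ndarray) -> float:
    """Max |Pearson r| at zero lag over all distinct pairs of rows.

    Returns 0.0 when there are fewer than two rows.
    """
    bits = np.asarray(bits, dtype=float)
    if bits.shape[0] < 2:
        return 0.0
    r = np.corrcoef(bits)
    iu = np.triu_indices(bits.shape[0], k=1)
    return float(np.abs(r[iu]).max())


def _draw_onsets(rng, duration, burst_rate, min_gap, flash_dur):
    """Sequential onsets: gap = min_gap + Exp(mean) with mean 1/rate - min_gap.

    When the refractory gap itself already dictates the rate (min_gap close
    to or above 1/rate, as with 0.35 s at 3 Hz), the exponential mean is
    clamped to a small jitter so flashes stay aperiodic while pacing at
    roughly the refractory period.
    """
    exp_mean = max(1.0 / burst_rate - min_gap, 0.02)
    onsets = [float(rng.uniform(0.0, 1.0 / burst_rate))]
    while True:
        t = onsets[-1] + min_gap + float(rng.exponential(exp_mean))
        if t + flash_dur > duration:
            break
        onsets.append(t)
    return np.asarray(onsets)


def generate_burst_codes(
    n_codes: int = 5,
    frame_rate: float = 60.0,
    duration: float = 2.2,
    burst_rate: float = 3.0,
    min_gap: float = 0.35,
    max_xcorr: float = 0.25,
    flash_frames: int = 4,
    seed: int = 0,
    max_attempts: int = 5000,
) -> CodeSet:
    """Rejection-sample a set of aperiodic burst codes.

    Onset gaps are ``min_gap`` plus an exponential draw whose mean is chosen
    so the realised flash rate is close to ``burst_rate``; candidates whose
    onset count deviates from ``burst_rate * duration`` by more than one, or
    whose zero-lag correlation with an already accepted code exceeds
    ``max_xcorr``, are rejected.  Each flash sets ``flash_frames`` consecutive
    frames to 1 (the stimulus patch stays visible for several frames), which
    yields roughly four non-flash samples for every flash sample at the
    default 3 Hz rate.

    Raises
    ------
    ValueError
        If ``min_gap * burst_rate > 1`` (no room for the exponential part).
    RuntimeError
        If the constraints cannot be satisfied within ``max_attempts``
        candidate draws, signalling over-constrained parameters.
    """
    if min_gap * burst_rate > 1.2:
        raise ValueError(
            "min_gap and burst_rate are inconsistent: the refractory gap "
            "alone caps the achievable rate well below burst_rate"
        )
    n_frames = int(round(duration * frame_rate))
    target = burst_rate * duration
    flash_dur = flash_frames / frame_rate
    rng = np.random.default_rng(seed)

    accepted: list[BurstCode] = []
    accepted_bits: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < n_codes:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not satisfy burst-code constraints within "
                f"{max_attempts} attempts (rate/gap/xcorr over-constrained)"
            )
        onsets = _draw_onsets(rng, duration, burst_rate, min_gap, flash_dur)
        if abs(onsets.size - target) > 1.0:
            continue
        frames = np.round(onsets * frame_rate).astype(int)
        if frames.size >= 2 and np.diff(frames).min() < int(
            np.floor(min_gap * frame_rate)
        ):
            continue
        bits = np.zeros(n_frames, dtype=np.uint8)
        for f in frames:
            bits[f : f + flash_frames] = 1
        if accepted_bits:
            cand = np.concatenate([np.stack(accepted_bits), bits[None]])
            if np.abs(np.corrcoef(cand)[-1, :-1]).max() > max_xcorr:
                continue
        accepted.append(
            BurstCode(
                bits=bits,
                frame_rate=frame_rate,
                duration=duration,
                onsets=frames / frame_rate,
            )
        )
        accepted_bits.append(bits)

    return CodeSet(
        codes=tuple(accepted),
        max_pairwise_xcorr=pairwise_zero_lag_xcorr(np.stack(accepted_bits)),
    )
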