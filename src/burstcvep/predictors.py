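"""Neurophysiological performance predictors and the screening regression.

Five predictors of decoding accuracy are computed from target (flash)
epochs: peak-to-peak amplitude of the average flash-VEP, latency of its
strongest peak, relative band power (delta/theta/alpha/beta), broadband SNR
against non-target epochs, and the mean Spearman correlation between target
epochs.  They can be measured in four spaces: BP (band-passed sensors, Oz
channel), AP (xDAWN components, first component), and their wavelet-space
counterparts BPWave/APWave (spectral predictors are undefined there).

The screening model regresses decoding accuracy on each predictor (OLS with
a Wald test on the slope), supporting a go/no-go decision from ~22 s of
calibration data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import statsmodels.api as sm
from scipy import signal as sps
from scipy import stats

from .preprocess import EpochSet
from .simulate import OZ
from .wavelets import WaveletFamily, gabor_envelopes

__all__ = [
    "PredictorProfile",
    "ScreeningModel",
    "peak_to_peak",
    "peak_latency",
    "relative_bandpower",
    "snr_predictor",
    "inter_epoch_correlation",
    "wavelet_space",
    "predictor_profile",
    "screen",
]

PSD_BAND = (1.0, 45.0)
BANDS_HZ = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 35.0)}
SPECTRAL_SPACES = ("BP", "AP")
WAVE_SPACES = ("BPWave", "APWave")


def _designated_row(space: str) -> int:
    """Row used for ERP-shape predictors: Oz in BP, first component in AP."""
    if space == "BP":
        return OZ
    if space in ("AP", "BPWave", "APWave"):
        return 0
    raise ValueError(f"unknown measurement space {space!r}")


def _series(epochs: EpochSet) -> np.ndarray:
    """Per-epoch 1-D series for p2p / latency / correlation predictors.

    Sensor/component spaces reduce to the designated row; wavelet spaces
    reduce to the pointwise maximum across wavelet envelopes.
    """
    if epochs.space_tag in WAVE_SPACES:
        return epochs.data.max(axis=1)
    return epochs.data[:, _designated_row(epochs.space_tag)]


def _check_targets(epochs: EpochSet) -> EpochSet:
    t = epochs.select(epochs.labels == 1)
    if len(t) == 0:
        raise ValueError("no target epochs")
    return t


def peak_to_peak(target_epochs: EpochSet) -> float:
    """Max - min of the averaged target epoch on the designated row."""
    t = _check_targets(target_epochs)
    avg = _series(t).mean(axis=0)
    return float(avg.max() - avg.min())


def peak_latency(target_epochs: EpochSet) -> float:
    """Time (s) of the maximum of |average target epoch|."""
    t = _check_targets(target_epochs)
    avg = _series(t).mean(axis=0)
    return float(np.argmax(np.abs(avg)) / target_epochs.fs)


def _welch_psd(data: np.ndarray, fs: float):
    """Welch PSD per epoch/row: full-epoch Hann segment, 4x zero padding.

    The 0.35 s epoch gives 2.9 Hz native resolution; zero padding refines
    the grid enough to read out the 1-4 Hz delta band.
    """
    nt = data.shape[-1]
    # detrend=False: the 1 Hz high-pass already removed the offset, and
    # per-segment mean removal would bias the delta band low at 0.35 s.
    return sps.welch(data, fs=fs, window="hann", nperseg=nt, nfft=4 * nt,
                     detrend=False, axis=-1)


def _psd_rows(epochs: EpochSet) -> np.ndarray:
    if epochs.space_tag == "BP":
        return epochs.data
    if epochs.space_tag == "AP":
        return epochs.data[:, :4]
    raise ValueError(
        "spectral predictors are not defined in wavelet spaces "
        f"(got {epochs.space_tag!r})"
    )


def relative_bandpower(epochs: EpochSet, band) -> float:
    """Mean PSD in ``band`` divided by the mean PSD over 1-45 Hz.

    ``band`` is a name ("delta".."beta") or an (lo, hi) pair inside 1-45 Hz.
    BP uses all channels; AP the first four components; averaged over epochs
    then rows.
    """
    if isinstance(band, str):
        band = BANDS_HZ[band]
    lo, hi = band
    if lo < PSD_BAND[0] or hi > PSD_BAND[1]:
        raise ValueError("band must lie within 1-45 Hz")
    data = _psd_rows(epochs)
    freqs, psd = _welch_psd(data, epochs.fs)
    psd = psd.mean(axis=(0, 1))  # over epochs then rows
    in_band = (freqs >= lo) & (freqs <= hi)
    broad = (freqs >= PSD_BAND[0]) & (freqs <= PSD_BAND[1])
    return float(psd[in_band].mean() / psd[broad].mean())


def snr_predictor(target_epochs: EpochSet, nontarget_epochs: EpochSet) -> float:
    """Broadband (1-45 Hz) PSD of target epochs over that of non-targets."""
    if len(target_epochs) == 0 or len(nontarget_epochs) == 0:
        raise ValueError("both target and non-target epochs are required")

    def broadband(e: EpochSet) -> float:
        freqs, psd = _welch_psd(_psd_rows(e), e.fs)
        sel = (freqs >= PSD_BAND[0]) & (freqs <= PSD_BAND[1])
        return float(psd.mean(axis=(0, 1))[sel].mean())

    return broadband(target_epochs) / broadband(nontarget_epochs)


def inter_epoch_correlation(target_epochs: EpochSet) -> float:
    """Mean Spearman correlation over all distinct pairs of target epochs."""
    t = _check_targets(target_epochs)
    series = _series(t)
    if len(series) < 2:
        raise ValueError("need at least 2 target epochs")
    ranks = np.apply_along_axis(stats.rankdata, 1, series)
    r = np.corrcoef(ranks)
    iu = np.triu_indices(len(series), k=1)
    return float(r[iu].mean())


def wavelet_space(epochs: EpochSet, family: WaveletFamily | None = None) -> EpochSet:
    """Map BP/AP epochs to the wavelet measurement space.

    The designated row is convolved with the Gabor family; the epoch's data
    become the stack of magnitude envelopes (n_wavelets x n_samples).
    """
    if epochs.space_tag not in SPECTRAL_SPACES:
        raise ValueError("wavelet_space expects BP or AP epochs")
    if family is None:
        family = WaveletFamily()
    row = epochs.data[:, _designated_row(epochs.space_tag)]
    env = gabor_envelopes(row, family, epochs.fs)
    tag = "BPWave" if epochs.space_tag == "BP" else "APWave"
    return epochs.with_data(env, tag)


@dataclasses.dataclass
class PredictorProfile:
    """The five predictor values for one participant in one space.

    Spectral fields (``rel_power``, ``snr``) are None in wavelet spaces.
    """

    participant_id: int
    space: str
    p2p_amplitude: float
    peak_latency: float
    inter_epoch_corr: float
    rel_power: dict | None = None
    snr: float | None = None

    def to_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "space": self.space,
            "p2p_amplitude": self.p2p_amplitude,
            "peak_latency": self.peak_latency,
            "inter_epoch_corr": self.inter_epoch_corr,
        }
        if self.rel_power is not None:
            for k, v in self.rel_power.items():
                d[f"rel_power_{k}"] = v
        if self.snr is not None:
            d["snr"] = self.snr
        return d


def predictor_profile(
    epochs: EpochSet, participant_id: int | None = None
) -> PredictorProfile:
    """All predictors available in the epochs' measurement space."""
    pid = int(epochs.participant_id[0]) if participant_id is None else participant_id
    targets = epochs.select(epochs.labels == 1)
    spectral = epochs.space_tag in SPECTRAL_SPACES
    rel_power = snr = None
    if spectral:
        rel_power = {b: relative_bandpower(epochs, b) for b in BANDS_HZ}
        snr = snr_predictor(targets, epochs.select(epochs.labels == 0))
    return PredictorProfile(
        participant_id=pid,
        space=epochs.space_tag,
        p2p_amplitude=peak_to_peak(epochs),
        peak_latency=peak_latency(epochs),
        inter_epoch_corr=inter_epoch_correlation(epochs),
        rel_power=rel_power,
        snr=snr,
    )


@dataclasses.dataclass
class ScreeningModel:
    """Univariate OLS screens of accuracy on each predictor.

    ``stats`` maps predictor name -> dict(slope, intercept, pearson_r,
    wald_p).  ``predict_accuracy`` / ``go`` use a chosen predictor's fit and
    the accuracy threshold separating low performers (default 0.70).
    """

    stats: dict
    decision_threshold: float = 0.70

    def predict_accuracy(self, predictor: str, value: float) -> float:
        s = self.stats[predictor]
        return s["intercept"] + s["slope"] * value

    def go(self, predictor: str, value: float) -> bool:
        return self.predict_accuracy(predictor, value) >= self.decision_threshold

    def best_predictor(self) -> str:
        return max(self.stats, key=lambda k: abs(self.stats[k]["pearson_r"]))


def screen(
    profiles: list[PredictorProfile] | "np.ndarray | dict",
    accuracies,
    decision_threshold: float = 0.70,
) -> ScreeningModel:
    """Fit the OLS/Wald screening regressions across participants.

    ``profiles`` may be a list of :class:`PredictorProfile` or a mapping of
    predictor name -> per-participant values.  Accuracies must lie in [0, 1]
    and at least 3 participants are required.
    """
    if isinstance(profiles, dict):
        table = {k: np.asarray(v, dtype=float) for k, v in profiles.items()}
    else:
        rows = [p.to_dict() for p in profiles]
        keys = [
            k for k in rows[0] if k not in ("participant_id", "space")
        ]
        table = {k: np.array([r[k] for r in rows], dtype=float) for k in keys}
    y = np.asarray(accuracies, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 participants")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("accuracies must lie in [0, 1]")

    out = {}
    for name, x in table.items():
        if len(x) != len(y):
            raise ValueError(f"length mismatch for predictor {name!r}")
        if np.std(x) == 0:
            raise ValueError(f"degenerate (constant) predictor {name!r}")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        out[name] = {
            "slope": float(res.params[1]),
            "intercept": float(res.params[0]),
            "pearson_r": float(np.corrcoef(x, y)[0, 1]),
            "wald_p": float(res.pvalues[1]),
        }
    return ScreeningModel(stats=out, decision_threshold=decision_threshold)
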