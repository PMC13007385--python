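"""Gabor wavelet filterbank shared by the GREEN decoder and the wavelet
measurement spaces.

Center frequencies are parameterized in octaves: f = 2**octave Hz, spanning
0 to ``max_octave`` (default 4.4, i.e. 1 to ~21.1 Hz).  Each wavelet is a
Gaussian-windowed complex exponential; its temporal extent is set by a
full-width-at-half-maximum per wavelet.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

__all__ = ["WaveletFamily", "gabor_kernels", "gabor_envelopes", "gabor_coefficients"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclasses.dataclass
class WaveletFamily:
    """A family of Gabor wavelets on an octave grid.

    ``center_octaves`` default to a uniform grid over [0, max_octave];
    ``fwhm`` (seconds) defaults to 1.5 cycles of each center frequency.
    ``learnable`` marks the family as trainable inside GREEN.
    """

    n_wavelets: int = 22
    max_octave: float = 4.4
    center_octaves: np.ndarray | None = None
    fwhm: np.ndarray | None = None
    n_cycles: float = 1.5
    learnable: bool = False

    def __post_init__(self) -> None:
        if self.center_octaves is None:
            self.center_octaves = np.linspace(0.0, self.max_octave, self.n_wavelets)
        self.center_octaves = np.asarray(self.center_octaves, dtype=float)
        self.n_wavelets = len(self.center_octaves)
        if (self.center_octaves < 0).any() or (
            self.center_octaves > self.max_octave + 1e-9
        ).any():
            raise ValueError("center octaves must lie in [0, max_octave]")
        if self.fwhm is None:
            self.fwhm = self.n_cycles / self.center_freqs_hz
        self.fwhm = np.asarray(self.fwhm, dtype=float)
        if (self.fwhm <= 0).any():
            raise ValueError("wavelet widths must be positive")

    @property
    def center_freqs_hz(self) -> np.ndarray:
        return 2.0 ** self.center_octaves


def gabor_kernels(family: WaveletFamily, fs: float, max_len: int | None = None):
    """Complex, L2-normalized kernels; truncated (with warning) at max_len."""
    kernels = []
    truncated = False
    for f, fwhm in zip(family.center_freqs_hz, family.fwhm):
        sigma = fwhm * _FWHM_TO_SIGMA
        half = int(np.ceil(3.0 * sigma * fs))
        if max_len is not None and 2 * half + 1 > max_len:
            truncated = True
            half = (max_len - 1) // 2
        t = np.arange(-half, half + 1) / fs
        k = np.exp(-0.5 * (t / sigma) ** 2) * np.exp(2j * np.pi * f * t)
        k /= np.linalg.norm(k)
        kernels.append(k)
    if truncated:
        warnings.warn("wavelet(s) longer than the epoch were truncated", stacklevel=2)
    return kernels


def gabor_coefficients(
    x: np.ndarray, family: WaveletFamily, fs: float, block: int = 512
) -> np.ndarray:
    """Complex Gabor coefficients, shape (..., n_wavelets, n_samples).

    'same'-mode convolution of each input row with each wavelet, via one
    FFT of the input shared across the whole family (epochs are processed
    in blocks to bound memory).
    """
    x = np.asarray(x, dtype=float)
    n_t = x.shape[-1]
    kernels = gabor_kernels(family, fs, max_len=n_t)
    max_m = max(k.size for k in kernels)
    L = next_fast_len(n_t + max_m - 1)
    kf = [fft(k, L) for k in kernels]
    flat = x.reshape(-1, n_t)
    out = np.empty((flat.shape[0], family.n_wavelets, n_t), dtype=complex)
    for s in range(0, flat.shape[0], block):
        xf = fft(flat[s : s + block], L, axis=-1)
        for j, (k, kfj) in enumerate(zip(kernels, kf)):
            full = ifft(xf * kfj, axis=-1)
            start = (k.size - 1) // 2  # 'same' alignment
            out[s : s + block, j] = full[:, start : start + n_t]
    return out.reshape(x.shape[:-1] + (family.n_wavelets, n_t))


def gabor_envelopes(x: np.ndarray, family: WaveletFamily, fs: float) -> np.ndarray:
    """Magnitude envelopes |Gabor coefficients|."""
    return np.abs(gabor_coefficients(x, family, fs))
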