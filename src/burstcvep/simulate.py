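"""Synthetic dry-EEG burst c-VEP sessions with known ground truth.

Each simulated participant attends 5 targets over 15 runs of 5 trials
(2.2 s each), every target cued exactly once per run.  The recorded signal is
the sum of

* a flash-locked evoked response: the cued code's onset impulse train, with
  per-flash amplitude and latency jitter, convolved with a biphasic
  (Ricker-style) template and projected through a fixed occipital spatial
  pattern;
* band-limited background oscillations (delta, theta, alpha, beta) realised as
  amplitude-randomised narrowband noise, independent per channel;
* pink (1/f) noise and white sensor noise.

Only the 2.2 s task trials are emitted (cue periods carry no data); trials
are laid out back to back so a session is 75 x 1100 samples at 500 Hz.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .codes import CodeSet, generate_burst_codes

__all__ = [
    "CHANNELS",
    "BANDS",
    "ParticipantSpec",
    "SimulatedSession",
    "erp_template",
    "simulate_session",
    "simulate_cohort",
    "default_spatial_pattern",
]

#: Electrode montage (occipito-parietal, dry 8-channel system).
CHANNELS = ("PO7", "O1", "Oz", "O2", "PO8", "PO3", "POz", "PO4")
OZ = CHANNELS.index("Oz")

#: Canonical EEG bands in Hz.
BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 35.0)}

N_RUNS = 15
TRIALS_PER_RUN = 5
TRIAL_DURATION = 2.2


def default_spatial_pattern() -> np.ndarray:
    """Unit-norm Oz-dominant scalp projection of the visual evoked source."""
    w = np.array([0.20, 0.35, 0.60, 0.35, 0.20, 0.25, 0.45, 0.25])
    return w / np.linalg.norm(w)


@dataclasses.dataclass
class ParticipantSpec:
    """Ground-truth generative parameters for one simulated participant.

    Amplitudes and noise SDs are in microvolts; latencies in seconds.
    ``band_powers`` maps band name -> RMS amplitude of that band's
    background oscillation (monotone proxy for relative band power).
    ``amplitude_jitter_sd`` is a fraction of the nominal ERP amplitude.
    """

    erp_amplitude: float = 5.0
    erp_peak_latency: float = 0.20
    erp_width: float = 0.04
    amplitude_jitter_sd: float = 0.3
    latency_jitter_sd: float = 0.01
    band_powers: dict = dataclasses.field(
        default_factory=lambda: {"delta": 2.0, "theta": 1.5, "alpha": 2.0, "beta": 1.0}
    )
    pink_noise_sd: float = 3.0
    sensor_noise_sd: float = 1.0
    spatial_pattern: np.ndarray = dataclasses.field(default_factory=default_spatial_pattern)
    seed: int = 0

    def __post_init__(self) -> None:
        self.spatial_pattern = np.asarray(self.spatial_pattern, dtype=float)
        if self.spatial_pattern.shape != (len(CHANNELS),):
            raise ValueError(f"spatial_pattern must have {len(CHANNELS)} entries")
        n = np.linalg.norm(self.spatial_pattern)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("spatial_pattern must have unit Euclidean norm")
        for name, v in [
            ("amplitude_jitter_sd", self.amplitude_jitter_sd),
            ("latency_jitter_sd", self.latency_jitter_sd),
            ("pink_noise_sd", self.pink_noise_sd),
            ("sensor_noise_sd", self.sensor_noise_sd),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spatial_pattern"] = self.spatial_pattern.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParticipantSpec":
        d = dict(d)
        d["spatial_pattern"] = np.asarray(d["spatial_pattern"], dtype=float)
        return cls(**d)


@dataclasses.dataclass
class SimulatedSession:
    """One participant's recording plus its trial schedule and ground truth.

    ``eeg`` is channels x samples (microvolts); ``schedule`` is a record
    array with fields run, trial, code_index, start_sample (0-based,
    half-open trial windows [start, start + trial_samples)).
    """

    eeg: np.ndarray
    schedule: np.ndarray
    code_set: CodeSet
    truth: ParticipantSpec
    fs: float = 500.0
    participant_id: int = 0

    @property
    def trial_samples(self) -> int:
        return int(round(TRIAL_DURATION * self.fs))

    @property
    def n_trials(self) -> int:
        return len(self.schedule)

    def trial_data(self, trial: int) -> np.ndarray:
        s = int(self.schedule["start_sample"][trial])
        return self.eeg[:, s : s + self.trial_samples]


def erp_template(amplitude: float, peak_latency: float, width: float = 0.04, fs: float = 500.0) -> np.ndarray:
    """Biphasic Ricker (Mexican-hat) flash-VEP template.

    Length is 0.35 s * fs samples.  The global extremum sits at
    ``peak_latency`` and the peak-to-peak value equals ``amplitude``.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if not 0 < peak_latency < 0.35:
        raise ValueError("peak_latency must lie in (0, 0.35) s")
    if width <= 0:
        raise ValueError("width must be positive")
    n = int(round(0.35 * fs))
    t = np.arange(n) / fs - peak_latency
    x = (t / width) ** 2
    w = (1.0 - x) * np.exp(-x / 2.0)
    # Ricker trough depth is 2 exp(-3/2); rescale to exact peak-to-peak.
    w *= amplitude / (w.max() - w.min())
    return w


def _pink_noise(rng, n_channels, n_samples, sd):
    """1/f-amplitude shaped Gaussian noise, std ``sd`` per channel."""
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    x *= sd / x.std(axis=1, keepdims=True)
    return x


def _band_noise(rng, n_channels, n_samples, fs, band, sd):
    """Narrowband Gaussian noise (FFT mask) with RMS ``sd`` per channel."""
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs < band[1])
    x = np.fft.irfft(spec * mask, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    x *= sd / std
    return x


def _make_schedule(rng, n_codes, trial_samples):
    rows = []
    for run in range(N_RUNS):
        order = rng.permutation(n_codes)
        for k, code in enumerate(order):
            trial = run * n_codes + k
            rows.append((run, trial, int(code), trial * trial_samples))
    return np.array(
        rows,
        dtype=[("run", "i4"), ("trial", "i4"), ("code_index", "i4"), ("start_sample", "i8")],
    )


def simulate_session(
    spec: ParticipantSpec,
    code_set: CodeSet | None = None,
    fs: float = 500.0,
    participant_id: int = 0,
) -> SimulatedSession:
    """Simulate one full 15-run session for ``spec``.

    Reproducible: the participant seed drives the cue order, all jitters and
    all noise draws.
    """
    if code_set is None:
        code_set = generate_burst_codes(seed=12345)
    rng = np.random.default_rng(spec.seed)
    trial_samples = int(round(TRIAL_DURATION * fs))
    n_codes = len(code_set)
    schedule = _make_schedule(rng, n_codes, trial_samples)
    n_samples = len(schedule) * trial_samples
    n_ch = len(CHANNELS)

    eeg = np.zeros((n_ch, n_samples))

    # Flash-locked evoked component (one source, fixed scalp pattern).
    if spec.erp_amplitude > 0:
        template = erp_template(1.0, spec.erp_peak_latency, spec.erp_width, fs)
        source = np.zeros(n_samples)
        for row in schedule:
            code = code_set[int(row["code_index"])]
            for onset in code.onsets:
                lat = onset + rng.normal(0.0, spec.latency_jitter_sd) if spec.latency_jitter_sd else onset
                amp = spec.erp_amplitude
                if spec.amplitude_jitter_sd:
                    amp *= max(0.0, 1.0 + rng.normal(0.0, spec.amplitude_jitter_sd))
                s0 = int(row["start_sample"]) + int(round(lat * fs))
                seg = source[s0 : s0 + template.size]
                seg += amp * template[: seg.size]
        eeg += spec.spatial_pattern[:, None] * source

    for band_name, sd in spec.band_powers.items():
        eeg += _band_noise(rng, n_ch, n_samples, fs, BANDS[band_name], sd)
    eeg += _pink_noise(rng, n_ch, n_samples, spec.pink_noise_sd)
    if spec.sensor_noise_sd:
        eeg += spec.sensor_noise_sd * rng.standard_normal((n_ch, n_samples))

    return SimulatedSession(
        eeg=eeg,
        schedule=schedule,
        code_set=code_set,
        truth=spec,
        fs=fs,
        participant_id=participant_id,
    )


def simulate_cohort(
    specs: list[ParticipantSpec],
    code_set: CodeSet | None = None,
    fs: float = 500.0,
) -> list[SimulatedSession]:
    """Independent sessions for several participants sharing one code set."""
    if code_set is None:
        code_set = generate_burst_codes(seed=12345)
    return [
        simulate_session(spec, code_set, fs=fs, participant_id=i)
        for i, spec in enumerate(specs)
    ]


def heterogeneous_cohort_specs(n: int = 24, base_seed: int = 0) -> list[ParticipantSpec]:
    """Cohort spanning realistic inter-participant variability.

    ERP amplitude, trial-to-trial jitter and background noise vary smoothly
    across participants so that decoding difficulty — and with it the
    neurophysiological predictors — spread over a wide range, mimicking the
    high-/low-performer split seen in dry-EEG cohorts.
    """
    rng = np.random.default_rng(base_seed)
    specs = []
    for i in range(n):
        u = i / max(n - 1, 1)  # 0 = hardest, 1 = easiest
        specs.append(
            ParticipantSpec(
                erp_amplitude=2.0 + 8.0 * u,
                erp_peak_latency=float(np.clip(0.20 + rng.normal(0, 0.015), 0.1, 0.3)),
                amplitude_jitter_sd=0.8 - 0.6 * u,
                latency_jitter_sd=0.02 - 0.015 * u,
                band_powers={
                    "delta": 3.0 - 1.5 * u,
                    "theta": 1.0 + 0.8 * u,
                    "alpha": 1.5 + 1.0 * u,
                    "beta": 1.0,
                },
                pink_noise_sd=4.0 - 2.0 * u,
                sensor_noise_sd=1.0,
                seed=base_seed + 1000 + i,
            )
        )
    return specs
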