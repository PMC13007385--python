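import numpy as np
import pytest

from burstcvep.codes import generate_burst_codes
from burstcvep.simulate import ParticipantSpec, simulate_session


@pytest.fixture(scope="session")
def code_set():
    return generate_burst_codes(seed=1)


@pytest.fixture(scope="session")
def midrange_session(code_set):
    """A realistic medium-difficulty participant."""
    spec = ParticipantSpec(
        erp_amplitude=8.0, amplitude_jitter_sd=0.2, latency_jitter_sd=0.005, seed=3
    )
    return simulate_session(spec, code_set)


@pytest.fixture(scope="session")
def noisefree_session(code_set):
    """All noise and jitter switched off: epochs are exact templates."""
    spec = ParticipantSpec(
        erp_amplitude=5.0,
        amplitude_jitter_sd=0.0,
        latency_jitter_sd=0.0,
        band_powers={"delta": 0.0, "theta": 0.0, "alpha": 0.0, "beta": 0.0},
        pink_noise_sd=0.0,
        sensor_noise_sd=0.0,
        seed=7,
    )
    return simulate_session(spec, code_set)


@pytest.fixture(scope="session")
def separable_epochs():
    """Linearly separable epoch fixture: rank-1 evoked source vs noise."""
    rng = np.random.default_rng(0)
    n, c, t = 300, 8, 175
    y = (np.arange(n) % 2).astype(int)
    pattern = rng.standard_normal(c)
    pattern /= np.linalg.norm(pattern)
    tmpl = np.sin(2 * np.pi * 7 * np.arange(t) / 500)
    X = 0.5 * rng.standard_normal((n, c, t))
    X[y == 1] += 3 * pattern[:, None] * tmpl[None, :]
    return X, y, pattern
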