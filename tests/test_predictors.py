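"""Neurophysiological predictors and the OLS/Wald screening regression."""

import dataclasses

import numpy as np
import pytest

from burstcvep.preprocess import EpochSet
from burstcvep.predictors import (
    inter_epoch_correlation,
    peak_latency,
    peak_to_peak,
    predictor_profile,
    relative_bandpower,
    screen,
    snr_predictor,
    wavelet_space,
)
from burstcvep.simulate import OZ
from burstcvep.wavelets import WaveletFamily


def _epochset(data, labels=None, space="BP", fs=500.0):
    n = len(data)
    labels = np.ones(n, int) if labels is None else np.asarray(labels)
    return EpochSet(
        data=np.asarray(data, float), labels=labels,
        class_index=np.zeros(n, int), trial_index=np.zeros(n, int),
        run_index=np.zeros(n, int), participant_id=np.zeros(n, int),
        onset_sample=np.arange(n), fs=fs, space_tag=space,
    )


class TestPeakToPeakAndLatency:
    def test_known_range_and_location(self):
        data = np.zeros((3, 8, 175))
        data[:, OZ, 100] = 5.0
        data[:, OZ, 50] = -3.0
        e = _epochset(data)
        assert peak_to_peak(e) == pytest.approx(8.0)
        assert peak_latency(e) == pytest.approx(100 / 500.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((10, 8, 175))
        e = _epochset(data)
        e2 = _epochset(2 * data)
        assert peak_to_peak(e2) == pytest.approx(2 * peak_to_peak(e))

    def test_negative_trough_latency(self):
        data = np.zeros((2, 8, 175))
        data[:, OZ, 80] = -9.0
        data[:, OZ, 120] = 4.0
        assert peak_latency(_epochset(data)) == pytest.approx(80 / 500.0)

    def test_empty_target_set_raises(self):
        e = _epochset(np.zeros((4, 8, 175)), labels=np.zeros(4, int))
        with pytest.raises(ValueError):
            peak_to_peak(e)


class TestRelativeBandpower:
    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(1)
        e = _epochset(rng.standard_normal((400, 8, 175)))
        vals = [relative_bandpower(e, b) for b in ("delta", "theta", "alpha", "beta")]
        # flat PSD: every band's relative power is ~1
        assert np.abs(np.array(vals) - 1.0).max() < 0.15

    def test_narrowband_alpha_dominates(self):
        t = np.arange(175) / 500.0
        data = np.tile(np.sin(2 * np.pi * 10 * t), (20, 8, 1))
        e = _epochset(data)
        alpha = relative_bandpower(e, "alpha")
        others = [relative_bandpower(e, b) for b in ("delta", "theta", "beta")]
        assert alpha > max(others)

    def test_band_outside_range_raises(self):
        e = _epochset(np.random.default_rng(2).standard_normal((5, 8, 175)))
        with pytest.raises(ValueError):
            relative_bandpower(e, (0.1, 4.0))

    def test_wavelet_space_has_no_spectral_predictors(self):
        rng = np.random.default_rng(3)
        e = _epochset(rng.standard_normal((5, 8, 175)))
        w = wavelet_space(e)
        with pytest.raises(ValueError):
            relative_bandpower(w, "alpha")


class TestSnr:
    def test_identical_sets_give_unity(self):
        rng = np.random.default_rng(4)
        e = _epochset(rng.standard_normal((30, 8, 175)))
        assert snr_predictor(e, e) == pytest.approx(1.0)

    def test_null_simulation_near_unity(self):
        rng = np.random.default_rng(5)
        a = _epochset(rng.standard_normal((300, 8, 175)))
        b = _epochset(rng.standard_normal((300, 8, 175)))
        assert snr_predictor(a, b) == pytest.approx(1.0, abs=0.05)

    def test_empty_raises(self):
        e = _epochset(np.zeros((3, 8, 175)))
        with pytest.raises(ValueError):
            snr_predictor(e.select(np.zeros(3, bool)), e)


class TestInterEpochCorrelation:
    def test_identical_epochs_unity(self):
        rng = np.random.default_rng(6)
        one = rng.standard_normal((1, 8, 175))
        e = _epochset(np.tile(one, (10, 1, 1)))
        assert inter_epoch_correlation(e) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(7)
        n = 80
        e = _epochset(rng.standard_normal((n, 8, 175)))
        rho = inter_epoch_correlation(e)
        se = 1.0 / np.sqrt(175)  # per-pair SE; the mean is tighter
        assert abs(rho) < 3 * se

    def test_needs_two_epochs(self):
        with pytest.raises(ValueError):
            inter_epoch_correlation(_epochset(np.zeros((1, 8, 175))))


class TestWaveletSpace:
    def test_zero_input_zero_envelopes(self):
        e = _epochset(np.zeros((3, 8, 175)))
        w = wavelet_space(e)
        assert w.space_tag == "BPWave"
        assert np.allclose(w.data, 0.0)

    def test_sinusoid_excites_matching_wavelet(self):
        fam = WaveletFamily(n_wavelets=8, max_octave=4.4)
        freqs = fam.center_freqs_hz
        j = 5
        t = np.arange(500) / 500.0
        data = np.zeros((2, 8, 500))
        data[:, OZ] = np.sin(2 * np.pi * freqs[j] * t)
        w = wavelet_space(_epochset(data), fam)
        means = w.data.mean(axis=(0, 2))
        assert means.argmax() == j

    def test_rejects_wavelet_input(self):
        e = _epochset(np.zeros((3, 8, 175)))
        w = wavelet_space(e)
        with pytest.raises(ValueError):
            wavelet_space(w)


@pytest.fixture(scope="module")
def cohort_epochs(code_set):
    from burstcvep.benchmark import prepare_session
    from burstcvep.simulate import ParticipantSpec, simulate_session

    def make(**kw):
        base = dict(erp_amplitude=6.0, amplitude_jitter_sd=0.2,
                    latency_jitter_sd=0.005, pink_noise_sd=2.0,
                    sensor_noise_sd=0.5, seed=31)
        base.update(kw)
        s = simulate_session(ParticipantSpec(**base), code_set)
        prep = prepare_session(s, stride=16)
        return prep.epochs

    return make


class TestParameterRecovery:
    """Predictors are monotone in the generator parameter they measure."""

    def test_p2p_monotone_in_amplitude(self, cohort_epochs):
        vals = [peak_to_peak(cohort_epochs(erp_amplitude=a))
                for a in (2.0, 5.0, 10.0, 20.0)]
        assert vals == sorted(vals)

    def test_latency_shift_recovered(self, cohort_epochs):
        a = peak_latency(cohort_epochs(erp_peak_latency=0.16))
        b = peak_latency(cohort_epochs(erp_peak_latency=0.20))
        assert (b - a) == pytest.approx(0.04, abs=0.01)

    def test_iec_decreasing_in_jitter(self, cohort_epochs):
        vals = [inter_epoch_correlation(cohort_epochs(amplitude_jitter_sd=j,
                                                      latency_jitter_sd=j / 30))
                for j in (0.0, 0.3, 1.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_snr_decreasing_in_sensor_noise(self, cohort_epochs):
        vals = []
        for ns in (0.5, 2.0, 6.0):
            e = cohort_epochs(sensor_noise_sd=ns)
            vals.append(snr_predictor(e.select(e.labels == 1),
                                      e.select(e.labels == 0)))
        assert vals[0] > vals[1] > vals[2]

    def test_alpha_power_monotone(self, cohort_epochs):
        vals = []
        for a in (0.5, 1.5, 3.0):
            e = cohort_epochs(erp_amplitude=0.01,
                              band_powers={"delta": 1.0, "theta": 1.0,
                                           "alpha": a, "beta": 1.0})
            vals.append(relative_bandpower(e, "alpha"))
        assert vals == sorted(vals)


class TestOrderInvariance:
    def test_predictors_invariant_to_epoch_order(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((40, 8, 175))
        labels = rng.integers(0, 2, 40)
        e = _epochset(data, labels=labels)
        perm = rng.permutation(40)
        ep = _epochset(data[perm], labels=labels[perm])
        assert peak_to_peak(e) == pytest.approx(peak_to_peak(ep))
        assert peak_latency(e) == pytest.approx(peak_latency(ep))
        assert inter_epoch_correlation(e) == pytest.approx(
            inter_epoch_correlation(ep))
        assert relative_bandpower(e, "alpha") == pytest.approx(
            relative_bandpower(ep, "alpha"))


class TestScreen:
    def test_perfect_linear_relation(self):
        x = np.linspace(0.1, 0.9, 12)
        model = screen({"p2p": x}, 0.1 + 0.8 * x)
        s = model.stats["p2p"]
        assert s["pearson_r"] == pytest.approx(1.0)
        assert s["wald_p"] < 1e-10
        assert s["slope"] == pytest.approx(0.8)

    def test_go_no_go_threshold(self):
        x = np.linspace(0.0, 1.0, 10)
        model = screen({"p2p": x}, x)
        assert model.go("p2p", 0.9)
        assert not model.go("p2p", 0.5)

    def test_degenerate_predictor_raises(self):
        with pytest.raises(ValueError):
            screen({"p2p": np.ones(10)}, np.linspace(0, 1, 10))

    def test_accuracy_range_checked(self):
        with pytest.raises(ValueError):
            screen({"p2p": np.arange(5.0)}, np.array([0.1, 0.5, 2.0, 0.2, 0.3]))

    def test_profile_to_screen_roundtrip(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, 50)
        e = _epochset(rng.standard_normal((50, 8, 175)), labels=labels)
        prof = predictor_profile(e)
        assert prof.space == "BP"
        assert set(prof.rel_power) == {"delta", "theta", "alpha", "beta"}
        profs = []
        for i in range(6):
            ei = _epochset(rng.standard_normal((50, 8, 175)) * (1 + i),
                           labels=rng.integers(0, 2, 50))
            p = predictor_profile(ei, participant_id=i)
            profs.append(p)
        model = screen(profs, np.linspace(0.3, 0.9, 6))
        assert "p2p_amplitude" in model.stats
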