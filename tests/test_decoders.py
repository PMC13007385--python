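"""The three epoch classifiers and the pretrain/fine-tune procedure."""

import numpy as np
import pytest
from sklearn.metrics import balanced_accuracy_score

from burstcvep import nn
from burstcvep.decoders import (
    CNNClassifier,
    GreenClassifier,
    SpdBlock,
    TSLDAClassifier,
    gabor_covariances,
    green_hyperparameter_grid,
    pretrain_finetune,
)
from burstcvep.geometry import riemannian_mean, tangent_vectors, untangent
from burstcvep.wavelets import WaveletFamily


class TestTSLDA:
    def test_tangent_dimension_closed_form(self, separable_epochs):
        X, y, _ = separable_epochs
        clf = TSLDAClassifier().fit(X, y)
        # 4 filtered + 4 prototype rows -> 8x8 SPD -> 36 tangent coords
        assert clf.lda_.coef_.shape[1] == 36

    def test_separable_fixture_learned(self, separable_epochs):
        X, y, _ = separable_epochs
        clf = TSLDAClassifier().fit(X, y)
        assert balanced_accuracy_score(y, clf.predict(X)) >= 0.99

    def test_probabilities_normalized(self, separable_epochs):
        X, y, _ = separable_epochs
        p = TSLDAClassifier().fit(X, y).predict_proba(X[:20])
        assert np.allclose(p.sum(axis=1), 1.0)
        assert (p >= 0).all()

    def test_deterministic(self, separable_epochs):
        X, y, _ = separable_epochs
        a = TSLDAClassifier(seed=0).fit(X, y).predict_proba(X[:50])
        b = TSLDAClassifier(seed=1).fit(X, y).predict_proba(X[:50])
        assert np.array_equal(a, b)

    def test_tangent_exp_log_inverse(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((6, 8, 8))
        covs = A @ A.transpose(0, 2, 1) + 8 * np.eye(8)
        ref = riemannian_mean(covs)
        assert np.abs(untangent(tangent_vectors(covs, ref), ref) - covs).max() < 1e-8


class TestCNN:
    def test_forward_softmax_normalized(self):
        clf = CNNClassifier(n_epochs=0, val_fraction=0)
        rng = np.random.default_rng(0)
        X = np.zeros((4, 8, 175))
        y = np.array([0, 1, 0, 1])
        clf.fit(X + rng.standard_normal(X.shape) * 0.01, y)
        p = clf.predict_proba(np.zeros((3, 8, 175)))
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_overfits_separable_fixture(self, separable_epochs):
        X, y, _ = separable_epochs
        clf = CNNClassifier(n_epochs=30, seed=0).fit(X[:200], y[:200])
        assert balanced_accuracy_score(y[:200], clf.predict(X[:200])) >= 0.99

    def test_inference_deterministic(self, separable_epochs):
        X, y, _ = separable_epochs
        clf = CNNClassifier(n_epochs=2, seed=0).fit(X, y)
        assert np.array_equal(clf.predict_proba(X[:30]), clf.predict_proba(X[:30]))

    def test_same_seed_same_model(self, separable_epochs):
        X, y, _ = separable_epochs
        a = CNNClassifier(n_epochs=2, seed=5).fit(X, y).predict_proba(X[:20])
        b = CNNClassifier(n_epochs=2, seed=5).fit(X, y).predict_proba(X[:20])
        assert np.array_equal(a, b)

    def test_too_short_epochs_raise(self):
        with pytest.raises(ValueError):
            CNNClassifier().fit(np.zeros((10, 8, 16)), np.zeros(10, int))


class TestGaborCovariances:
    def test_white_noise_near_diagonal(self):
        """Off-diagonals vanish at 3 SE for independent channels.

        Narrowband filtering leaves ~T / (2 sigma_t fs) independent samples
        per wavelet, so the whiteness tolerance is per-wavelet.
        """
        rng = np.random.default_rng(1)
        T = 20000
        X = rng.standard_normal((1, 4, T))
        fam = WaveletFamily(n_wavelets=5, max_octave=4.0)
        C = gabor_covariances(X, fam, 500.0)[0]
        sigma_t = fam.fwhm / 2.355
        for j in range(5):
            d = np.diag(C[j])
            n_eff = T / (2.0 * sigma_t[j] * 500.0)
            iu = np.triu_indices(4, k=1)
            se = np.sqrt(d[iu[0]] * d[iu[1]] / n_eff)
            assert (np.abs(C[j][iu]) < 3 * se).all()

    def test_sinusoid_tuning_curve(self):
        fam = WaveletFamily(n_wavelets=8, max_octave=4.4)
        t = np.arange(2000) / 500.0
        j = 4
        X = np.sin(2 * np.pi * fam.center_freqs_hz[j] * t)[None, None, :]
        X = np.tile(X, (1, 3, 1))
        C = gabor_covariances(X, fam, 500.0)[0]
        traces = np.trace(C, axis1=-2, axis2=-1)
        assert traces.argmax() == j

    def test_zero_input_shrinkage_floor(self):
        fam = WaveletFamily(n_wavelets=3)
        C = gabor_covariances(np.zeros((2, 4, 175)), fam, 500.0, shrinkage=0.1)
        assert np.allclose(C, 0.0)  # tr(0) floor is 0; SPD-ness comes from ReEig


class TestSpdBlock:
    def _spd(self, rng, k=6, d=7):
        A = rng.standard_normal((k, d, d))
        return A @ A.transpose(0, 2, 1) + 2 * np.eye(d)

    def test_output_spd_with_floored_eigenvalues(self):
        rng = np.random.default_rng(2)
        block = SpdBlock(7, 4, rng=rng)
        out = block(nn.Tensor(self._spd(rng))).data
        assert out.shape == (6, 4, 4)
        assert np.linalg.eigvalsh(out).min() >= block.eps - 1e-12

    def test_alpha_one_gives_scaled_identity(self):
        rng = np.random.default_rng(3)
        block = SpdBlock(7, 4, rng=rng)
        block.rho.data = np.array(50.0)  # sigmoid -> 1
        C = self._spd(rng, k=1)
        out = block(nn.Tensor(C)).data[0]
        mu = np.trace(C[0]) / 7.0
        assert np.allclose(out, mu * block.W.data.T @ block.W.data, atol=1e-6)

    def test_identity_path(self):
        rng = np.random.default_rng(4)
        block = SpdBlock(7, 4, alpha0=1e-9, rng=rng)
        block.rho.data = np.array(-60.0)  # alpha -> 0
        block.W.data = np.eye(7)[:, :4]
        C = self._spd(rng, k=1)
        out = block(nn.Tensor(C)).data[0]
        assert np.allclose(out, C[0][:4, :4], atol=1e-8)

    def test_retraction_restores_stiefel(self):
        rng = np.random.default_rng(5)
        block = SpdBlock(7, 4, rng=rng)
        block.W.data += 0.3 * rng.standard_normal(block.W.shape)
        block.retract()
        assert np.allclose(block.W.data.T @ block.W.data, np.eye(4), atol=1e-10)


class TestGreen:
    def test_tangent_feature_length(self):
        # 4x4 SPD -> 10 coords; 22 wavelets -> 220 features
        assert 4 * 5 // 2 == 10
        clf = GreenClassifier(n_epochs=0, val_fraction=0)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 6, 175))
        clf.fit(X, (np.arange(8) % 2))
        assert clf._d1.W.shape[0] == 22 * 10

    def test_hyperparameter_grid_size(self):
        grid = green_hyperparameter_grid()
        assert len(grid) == 13 * 5 * 8 == 520

    def test_overfits_separable_fixture(self, separable_epochs):
        X, y, _ = separable_epochs
        clf = GreenClassifier(n_epochs=30, seed=0).fit(X[:200], y[:200])
        assert balanced_accuracy_score(y[:200], clf.predict(X[:200])) >= 0.99

    def test_spd_preserved_through_forward(self):
        rng = np.random.default_rng(6)
        clf = GreenClassifier(n_epochs=0, val_fraction=0, n_wavelets=5)
        X = rng.standard_normal((6, 4, 175))
        clf.fit(X, (np.arange(6) % 2))
        C = gabor_covariances(X, clf.family_, 500.0)
        S = clf.spd_(nn.Tensor(C)).data
        assert np.linalg.eigvalsh(S).min() > 0

    def test_seeded_determinism(self, separable_epochs):
        X, y, _ = separable_epochs
        a = GreenClassifier(n_epochs=2, seed=9).fit(X, y).predict_proba(X[:20])
        b = GreenClassifier(n_epochs=2, seed=9).fit(X, y).predict_proba(X[:20])
        assert np.array_equal(a, b)

    def test_learnable_wavelets_move(self):
        rng = np.random.default_rng(7)
        X = 0.3 * rng.standard_normal((40, 4, 100))
        y = (np.arange(40) % 2).astype(int)
        X[y == 1] += np.sin(2 * np.pi * 8 * np.arange(100) / 500)
        clf = GreenClassifier(n_wavelets=4, n_epochs=3, batch_size=16,
                              val_fraction=0, learn_wavelets=True, seed=0)
        init = np.linspace(0, 4.4, 4)
        clf.fit(X, y)
        assert np.abs(clf._oct.data - init).max() > 1e-8
        assert np.allclose(clf.spd_.W.data.T @ clf.spd_.W.data, np.eye(4), atol=1e-8)


class TestProbabilityCalibration:
    def test_balanced_noise_centered_probabilities(self):
        """On label-balanced pure noise the mean P(flash) stays near 0.5.

        The gradient models run at their default training budget (the loss
        optimum on symmetric noise is the centered softmax); early stopping
        is off since a tiny validation split only adds selection noise.
        """
        rng = np.random.default_rng(8)
        X = rng.standard_normal((400, 8, 175))
        y = (np.arange(400) % 2).astype(int)
        for clf in (TSLDAClassifier(),
                    GreenClassifier(val_fraction=0.0, seed=0),
                    CNNClassifier(val_fraction=0.0, seed=0)):
            p = clf.fit(X, y).predict_proba(X)[:, 1]
            assert 0.45 <= p.mean() <= 0.55


class TestPretrainFinetune:
    def test_zero_steps_identity(self, separable_epochs):
        X, y, _ = separable_epochs
        clf = CNNClassifier(n_epochs=2, seed=0)
        m = pretrain_finetune(clf, X[:150], y[:150], X[150:], y[150:],
                              finetune_epochs=0)
        ref = CNNClassifier(n_epochs=2, seed=0).fit(X[:150], y[:150])
        assert np.array_equal(m.predict_proba(X[:30]), ref.predict_proba(X[:30]))

    def test_finetuning_improves_on_shifted_target(self):
        """Adapting to a rotated target domain beats the source-only model."""
        rng = np.random.default_rng(9)
        n, c, t = 240, 6, 100
        tmpl = np.sin(2 * np.pi * 9 * np.arange(t) / 500)
        y = (np.arange(n) % 2).astype(int)

        def domain(pattern, seed):
            r = np.random.default_rng(seed)
            X = 0.8 * r.standard_normal((n, c, t))
            X[y == 1] += 2.0 * pattern[:, None] * tmpl
            return X

        p_src = np.eye(c)[0]
        p_tgt = np.eye(c)[3]  # different spatial mixing
        Xs, Xt = domain(p_src, 1), domain(p_tgt, 2)
        src_only = GreenClassifier(n_epochs=6, seed=0).fit(Xs, y)
        adapted = pretrain_finetune(
            GreenClassifier(n_epochs=6, seed=0), Xs, y, Xt[:80], y[:80])
        acc_src = balanced_accuracy_score(y[80:], src_only.predict(Xt[80:]))
        acc_ft = balanced_accuracy_score(y[80:], adapted.predict(Xt[80:]))
        assert acc_ft >= acc_src

    def test_unsupported_model_raises(self):
        class Dummy:
            pass

        with pytest.raises(TypeError):
            pretrain_finetune(Dummy(), None, None, None, None)
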