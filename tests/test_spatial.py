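"""xDAWN filtering, super epochs and Riemannian alignment."""

import numpy as np
import pytest
from scipy.linalg import eigh

from burstcvep.geometry import airm_distance, lw_covariances, riemannian_mean
from burstcvep.spatial import (
    CompletePreprocessor,
    RiemannianAlignment,
    SuperEpochBuilder,
    Xdawn,
)


def _rank1_epochs(rng, n=400, c=8, t=175, noise=0.01, snr=1.0):
    pattern = rng.standard_normal(c)
    pattern /= np.linalg.norm(pattern)
    tmpl = np.sin(2 * np.pi * 9 * np.arange(t) / 500) * np.hanning(t)
    y = (np.arange(n) % 2).astype(int)
    X = noise * rng.standard_normal((n, c, t))
    X[y == 1] += snr * pattern[:, None] * tmpl
    return X, y, pattern


class TestXdawn:
    def test_recovers_known_mixing_vs_gevd_oracle(self):
        """First filter matches a dense generalized-eigenvalue solve."""
        rng = np.random.default_rng(0)
        X, y, pattern = _rank1_epochs(rng)
        xd = Xdawn(n_components=4).fit(X, y)
        # independent dense oracle
        c = X.shape[1]
        erp = X[y == 1].mean(0)
        C1 = erp @ erp.T / X.shape[2]
        flat = X.transpose(1, 0, 2).reshape(c, -1)
        Cx = flat @ flat.T / flat.shape[1]
        Cx = Cx + 1e-9 * np.trace(Cx) * np.eye(c)
        _, V = eigh(C1, Cx)
        u = V[:, -1] / np.linalg.norm(V[:, -1])
        assert abs(u @ xd.filters_[:, 0]) >= 0.999
        # forward pattern points along the true mixing direction
        p = xd.patterns_[:, 0] / np.linalg.norm(xd.patterns_[:, 0])
        assert abs(p @ pattern) >= 0.999

    def test_full_rank_filters_invertible(self, separable_epochs):
        X, y, _ = separable_epochs
        xd = Xdawn(n_components=8).fit(X, y)
        assert np.linalg.matrix_rank(xd.filters_) == 8

    def test_label_shuffle_drops_evoked_ratio(self, separable_epochs):
        X, y, _ = separable_epochs
        true_ratio = Xdawn(4).fit(X, y).eigenvalues_[0]
        rng = np.random.default_rng(1)
        perm_ratio = Xdawn(4).fit(X, rng.permutation(y)).eigenvalues_[0]
        assert perm_ratio < true_ratio

    def test_energy_ordering(self, separable_epochs):
        X, y, _ = separable_epochs
        ev = Xdawn(4).fit(X, y).eigenvalues_
        assert (np.diff(ev) <= 1e-12).all()

    def test_transform_shapes_and_linearity(self, separable_epochs):
        X, y, _ = separable_epochs
        xd = Xdawn(4).fit(X, y)
        Z = xd.transform(X)
        assert Z.shape == (len(X), 4, X.shape[2])
        assert np.allclose(xd.transform(np.zeros_like(X[:1])), 0.0)
        with pytest.raises(ValueError):
            xd.transform(X[:, :5])

    def test_projection_reconstruction_on_rank_k_data(self):
        """patterns @ filtered reconstructs rank-limited data to noise floor."""
        rng = np.random.default_rng(2)
        X, y, _ = _rank1_epochs(rng, noise=1e-3)
        xd = Xdawn(4).fit(X, y)
        Z = xd.transform(X[y == 1])
        recon = np.einsum("ck,nkt->nct", xd.patterns_, Z)
        err = np.abs(recon - X[y == 1]).mean()
        assert err < 5e-3

    def test_agrees_with_mne_reference_implementation(self):
        """Independent cross-check against mne's Xdawn transformer."""
        mne_decoding = pytest.importorskip("mne.decoding")
        import logging

        logging.disable(logging.CRITICAL)
        rng = np.random.default_rng(10)
        X, y, _ = _rank1_epochs(rng, noise=0.05)
        ref = mne_decoding.XdawnTransformer(n_components=2).fit(X, y)
        ours = Xdawn(2).fit(X, y)
        f = ref.filters_[1][0]  # event-class leading filter
        f = f / np.linalg.norm(f)
        logging.disable(logging.NOTSET)
        assert abs(f @ ours.filters_[:, 0]) > 0.999

    def test_fit_records_toeplitz_route_agrees(self, noisefree_session):
        """Continuous-record least-squares fit matches the epoch route."""
        from burstcvep.preprocess import slice_epochs

        s = noisefree_session
        epochs = slice_epochs(s, stride_samples=4)
        a = Xdawn(2).fit(epochs.data, epochs.labels)
        records, onsets = [], []
        for row in s.schedule:
            records.append(s.trial_data(int(row["trial"])))
            code = s.code_set[int(row["code_index"])]
            onsets.append(np.round(code.onsets * s.fs).astype(int))
        b = Xdawn(2).fit_records(records, onsets, 175)
        assert abs(a.filters_[:, 0] @ b.filters_[:, 0]) > 0.99


class TestSuperEpochs:
    def test_row_layout(self, separable_epochs):
        X, y, _ = separable_epochs
        Z = Xdawn(4).fit(X, y).transform(X)
        sb = SuperEpochBuilder().fit(Z, y)
        S = sb.transform(Z)
        assert S.shape == (len(Z), 7, X.shape[2])  # 3 epoch + 4 evoked rows
        # evoked rows identical across epochs
        assert np.ptp(S[:, 3:], axis=0).max() == 0.0

    def test_evoked_from_calibration_only(self, separable_epochs):
        X, y, _ = separable_epochs
        Z = Xdawn(4).fit(X, y).transform(X)
        sb = SuperEpochBuilder().fit(Z[:100], y[:100])
        a = sb.transform(Z[100:])[:, 3:]
        b = sb.transform(Z[100:] * 5.0)[:, 3:]  # test data changes ...
        assert np.array_equal(a, b)  # ... evoked rows do not

    def test_identical_target_epochs_evoked_equals_epoch(self):
        rng = np.random.default_rng(3)
        Z = np.tile(rng.standard_normal((1, 4, 50)), (10, 1, 1))
        y = np.ones(10, int)
        S = SuperEpochBuilder().fit(Z, y).transform(Z)
        assert np.allclose(S[:, :3], S[:, 3:6])

    def test_no_targets_raises(self):
        with pytest.raises(ValueError):
            SuperEpochBuilder().fit(np.zeros((5, 4, 20)), np.zeros(5, int))


class TestRiemannianAlignment:
    def test_whitening_identity_mean(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 7, 175)) * rng.uniform(0.5, 2, (1, 7, 1))
        A = rng.standard_normal((7, 7))
        X = np.einsum("rc,nct->nrt", A, X)
        al = RiemannianAlignment(mode="whiten").fit(X)
        M = riemannian_mean(
            al.transform_covariances(lw_covariances(X)), tol=1e-10, max_iter=200
        )
        assert np.linalg.norm(M - np.eye(7)) <= 1e-6

    def test_identity_mean_is_identity_map(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 4, 300))
        for mode in ("whiten", "literal"):
            al = RiemannianAlignment(mode=mode).fit(X)
            al.mean_ = np.eye(4)
            al.transport_ = np.eye(4)
            assert np.allclose(al.transform(X), X)

    def test_literal_mode_multiplies_by_mean(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 4, 200))
        al = RiemannianAlignment(mode="literal").fit(X)
        assert np.allclose(al.transform(X[:2]), al.mean_ @ X[:2])

    def test_alignment_reduces_cross_participant_distance(self):
        """Per-participant whitening brings covariance means together."""
        rng = np.random.default_rng(7)
        base = rng.standard_normal((50, 5, 200))
        d_before, d_after = [], []
        A1 = np.eye(5) + 0.5 * rng.standard_normal((5, 5))
        A2 = np.eye(5) + 0.5 * rng.standard_normal((5, 5))
        X1 = np.einsum("rc,nct->nrt", A1, base)
        X2 = np.einsum("rc,nct->nrt", A2, rng.standard_normal((50, 5, 200)))
        m1 = riemannian_mean(lw_covariances(X1))
        m2 = riemannian_mean(lw_covariances(X2))
        d_before = airm_distance(m1, m2)
        w1 = RiemannianAlignment().fit(X1)
        w2 = RiemannianAlignment().fit(X2)
        m1w = riemannian_mean(w1.transform_covariances(lw_covariances(X1)))
        m2w = riemannian_mean(w2.transform_covariances(lw_covariances(X2)))
        d_after = airm_distance(m1w, m2w)
        assert d_after < d_before

    def test_refit_whitening_idempotent(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 4, 250))
        al = RiemannianAlignment().fit(X)
        Xw = al.transform(X)
        al2 = RiemannianAlignment().fit(Xw)
        # second whitening on already-aligned data is near identity
        assert np.abs(al2.transport_ - np.eye(4)).max() < 0.15
        assert np.abs(al2.transform(Xw) - Xw).max() < 0.2 * np.abs(Xw).max()

    def test_empty_calibration_raises(self):
        with pytest.raises(ValueError):
            RiemannianAlignment().fit(np.zeros((0, 4, 100)))

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            RiemannianAlignment(mode="nope").fit(np.random.default_rng(0).standard_normal((5, 3, 100)))


class TestCompletePreprocessor:
    def test_end_to_end_shapes_and_provenance(self, separable_epochs):
        X, y, _ = separable_epochs
        pre = CompletePreprocessor().fit(X[:150], y[:150])
        S = pre.transform(X)
        assert S.shape == (len(X), 7, X.shape[2])
        Z = pre.transform_components(X)
        assert Z.shape == (len(X), 4, X.shape[2])

    def test_drop_leading_components_shifts(self, separable_epochs):
        X, y, _ = separable_epochs
        pre0 = CompletePreprocessor().fit(X, y)
        pre1 = CompletePreprocessor(drop_leading_components=1).fit(X, y)
        z0 = pre0.transform_components(X[:3])
        z1 = pre1.transform_components(X[:3])
        assert z0.shape == z1.shape  # still 4 components, shifted by one
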