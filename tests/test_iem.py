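"""Inverted encoding model: basis, inversion algebra, circular summaries."""
import numpy as np
import pytest
from sklearn.covariance import ledoit_wolf as sk_ledoit_wolf

import tempocontext as tc
from tempocontext import iem
from tempocontext.containers import SensorEpochs

from conftest import wrapped_abs_error


class TestBasis:
    def test_peak_value_one(self):
        basis = iem.make_basis()
        for phi in basis.phis:
            assert basis(np.array([phi]))[list(basis.phis).index(phi), 0] \
                == pytest.approx(1.0)

    def test_half_rectification_zero_at_90(self):
        basis = iem.make_basis()
        vals = basis(np.array([90.0]))
        assert vals[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_sum_translationally_symmetric(self):
        basis = iem.make_basis()
        theta = np.linspace(0, 360, 720, endpoint=False)
        total = basis(theta).sum(axis=0)
        shifted = basis(theta + 72.0).sum(axis=0)
        np.testing.assert_allclose(total, shifted, atol=1e-12)

    def test_half_angle_is_circular(self):
        basis = iem.make_basis(exponent=6, half_angle=True)
        a = basis(np.array([359.0]))
        b = basis(np.array([-1.0]))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            iem.make_basis(exponent=0)


class TestChannelResponses:
    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(0)
        basis = iem.make_basis()
        angles = rng.uniform(0, 360, 40)
        C = iem.channel_responses(angles, basis)
        for k, phi in enumerate(basis.phis):
            for j, th in enumerate(angles):
                d = (th - phi + 180) % 360 - 180
                expect = max(0.0, np.cos(np.radians(d))) ** 5
                assert C[k, j] == pytest.approx(expect, abs=1e-12)
        assert np.all((0 <= C) & (C <= 1))

    def test_opposite_presentations_disjoint_support(self):
        basis = iem.make_basis()
        C = iem.channel_responses(np.array([0.0, 180.0]), basis)
        assert np.all(C[:, 0] * C[:, 1] == 0)


class TestFitWeights:
    def test_zero_data_zero_weights(self):
        basis = iem.make_basis()
        C = basis(np.linspace(0, 360, 50, endpoint=False))
        Cd = C - C.mean(axis=1, keepdims=True)
        W, eps = iem.fit_weights(np.zeros((6, 50)), Cd)
        assert np.all(W == 0)

    def test_projection_identity_per_channel(self):
        rng = np.random.default_rng(1)
        basis = iem.make_basis()
        angles = np.linspace(0, 360, 80, endpoint=False)
        C = basis(angles)
        Cd = C - C.mean(axis=1, keepdims=True)
        Wt = rng.normal(size=(7, 5))
        B = Wt @ Cd
        W, eps = iem.fit_weights(B, Cd)
        for i in range(5):
            ci = Cd[i]
            np.testing.assert_allclose(W[:, i], B @ ci / (ci @ ci), atol=1e-12)
            np.testing.assert_allclose(eps[i], B - np.outer(W[:, i], ci),
                                       atol=1e-12)

    def test_orthogonal_channels_match_joint_ls(self):
        rng = np.random.default_rng(2)
        n = 60
        C = rng.normal(size=(4, n))
        C = np.linalg.qr(C.T)[0].T  # orthonormal rows
        Wt = rng.normal(size=(6, 4))
        B = Wt @ C
        W, _ = iem.fit_weights(B, C)
        W_joint = np.linalg.lstsq(C.T, B.T, rcond=None)[0].T
        np.testing.assert_allclose(W, W_joint, atol=1e-9)


class TestShrinkageCovariance:
    def test_large_sample_shrinkage_vanishes(self):
        # non-spherical noise: the analytic intensity is O(1/n)
        rng = np.random.default_rng(3)
        eps = rng.normal(size=(5, 20_000)) * np.array([1, 1, 2, 3, 5.0])[:, None]
        Sigma, lam, nu = iem.regularized_noise_cov(eps)
        assert lam < 0.02
        np.testing.assert_allclose(Sigma, eps @ eps.T / (20_000 - 1),
                                   rtol=0.05, atol=0.05)

    def test_tiny_sample_still_positive_definite(self):
        rng = np.random.default_rng(4)
        eps = rng.normal(size=(20, 2))
        Sigma, lam, nu = iem.regularized_noise_cov(eps)
        eig = np.linalg.eigvalsh(Sigma)
        assert eig.min() > 0
        assert eig.min() >= lam * nu - 1e-12

    def test_intensity_always_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = rng.integers(2, 12)
            n = rng.integers(2, 30)
            eps = rng.standard_t(3, size=(m, n))
            _, lam, _ = iem.regularized_noise_cov(eps)
            assert 0.0 <= lam <= 1.0

    def test_matches_sklearn_ledoit_wolf(self):
        rng = np.random.default_rng(6)
        eps = rng.normal(size=(6, 500)) * np.arange(1, 7)[:, None]
        _, lam, _ = iem.regularized_noise_cov(eps)
        _, lam_sk = sk_ledoit_wolf(eps.T, assume_centered=True)
        assert lam == pytest.approx(lam_sk, abs=0.01)

    def test_no_shrinkage_singular_raises(self):
        rng = np.random.default_rng(7)
        eps = rng.normal(size=(10, 5))
        with pytest.raises(np.linalg.LinAlgError):
            iem.regularized_noise_cov(eps, shrinkage=None)


class TestSpatialFilters:
    def test_identity_covariance(self):
        rng = np.random.default_rng(8)
        W = rng.normal(size=(6, 3))
        Sigmas = [np.eye(6)] * 3
        V = iem.spatial_filters(W, Sigmas)
        for i in range(3):
            np.testing.assert_allclose(V[i], W[:, i] / (W[:, i] @ W[:, i]),
                                       atol=1e-12)

    def test_normalization_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = 8
            W = rng.normal(size=(m, 5))
            A = rng.normal(size=(m, m))
            Sigmas = [A @ A.T + np.eye(m) for _ in range(5)]
            V = iem.spatial_filters(W, Sigmas)
            for i in range(5):
                assert V[i] @ W[:, i] == pytest.approx(1.0, abs=1e-9)

    def test_single_channel_noiseless_recovery(self):
        rng = np.random.default_rng(10)
        w = rng.normal(size=5)
        c = rng.normal(size=30)
        B = np.outer(w, c)
        V = iem.spatial_filters(w[:, None], [np.eye(5)])
        np.testing.assert_allclose(V[0] @ B, c, atol=1e-9)


class TestVectorDecode:
    def test_matches_brute_force_phasor(self):
        rng = np.random.default_rng(11)
        basis = iem.make_basis()
        c = rng.random((5, 50))
        out = iem.vector_decode(c, basis)
        phis = np.radians(basis.phis)
        z = (c * np.exp(1j * phis)[:, None]).sum(axis=0)
        expect = np.degrees(np.angle(z)) % 360.0
        np.testing.assert_allclose(out, expect, atol=1e-9)

    def test_single_channel_peaks_at_its_angle(self):
        basis = iem.make_basis()
        c = np.zeros(5)
        c[2] = 1.0
        assert iem.vector_decode(c, basis) == pytest.approx(basis.phis[2])

    def test_uniform_channels_undefined(self):
        basis = iem.make_basis()
        with pytest.warns(UserWarning):
            out = iem.vector_decode(np.ones(5), basis)
        assert np.isnan(out)

    def test_printed_basis_alias_is_bounded(self):
        # deterministic aliasing of the rectified fifth-power basis through
        # the phasor decoder: large at five channels, frozen here
        basis = iem.make_basis()
        theta = np.linspace(0, 360, 720, endpoint=False)
        decoded = np.asarray(iem.vector_decode(basis(theta), basis))
        err = wrapped_abs_error(decoded, theta)
        assert 13.0 < err.max() < 14.0

    def test_band_limited_basis_decodes_exactly(self):
        basis = iem.make_basis(exponent=6, half_angle=True)
        theta = np.linspace(0, 360, 720, endpoint=False)
        decoded = np.asarray(iem.vector_decode(basis(theta), basis))
        assert wrapped_abs_error(decoded, theta).max() < 1e-6

    def test_angle_doubling_path(self):
        # doubled-angle decoding is 180-deg periodic and carries the same
        # rectified-basis alias (halved in the angle domain)
        basis = iem.make_basis(periodicity=2)
        c = basis(np.array([40.0]))
        out = float(np.asarray(iem.vector_decode(c, basis)).ravel()[0])
        assert 0.0 <= out < 180.0
        err = min(abs(out - 40.0), abs(out - 40.0 + 180), abs(out - 40.0 - 180))
        assert err < 8.0


class TestCircularSummaries:
    def test_perfect_consensus(self):
        th = np.linspace(0, 360, 100, endpoint=False)
        acc = iem.decoding_accuracy(th, th)
        prec = iem.decoding_precision(th, th)
        assert acc.pooled == pytest.approx(1.0)
        assert prec.pooled == pytest.approx(1.0)

    def test_opposite_decodes(self):
        th = np.linspace(0, 360, 100, endpoint=False)
        acc = iem.decoding_accuracy((th + 180.0) % 360.0, th)
        assert acc.pooled == pytest.approx(-1.0)

    def test_precision_printed_formula_values(self):
        # |R| = 0.5 -> sigma = 1, printed precision = 1 - sqrt(2)
        th = np.zeros(2)
        decoded = np.array([0.0, 120.0])  # two phasors 120 deg apart: |R| = 1/2
        R = np.abs(np.mean(np.exp(1j * np.radians(decoded))))
        assert R == pytest.approx(0.5, abs=1e-12)
        prec = iem.decoding_precision(decoded, th, n_bins=1)
        assert prec.values[0] == pytest.approx(1.0 - np.sqrt(2.0))

    def test_uniform_precision_variants(self):
        th = np.zeros(8)
        decoded = np.arange(0, 360, 45.0)
        printed = iem.decoding_precision(decoded, th, n_bins=1)
        rescaled = iem.decoding_precision(decoded, th, n_bins=1,
                                          variant="rescaled")
        assert printed.values[0] == pytest.approx(-1.0)
        assert rescaled.values[0] == pytest.approx(0.0)

    def test_bias_constant_offset(self):
        th = np.linspace(0, 360, 60, endpoint=False)
        b = iem.decoding_bias((th + 10.0) % 360.0, th)
        np.testing.assert_allclose(
            b.values[np.isfinite(b.values)], 10.0, atol=1e-9)

    def test_bias_matches_brute_force_circular_mean(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(5, 40)
            th = rng.uniform(0, 360, n)
            err = rng.normal(0, 40, n)
            b = iem.decoding_bias((th + err) % 360, th, n_bins=1)
            expect = np.degrees(np.angle(np.mean(
                np.exp(1j * np.radians(err)))))
            assert b.values[0] == pytest.approx(expect, abs=1e-9)

    def test_global_rotation_invariance(self):
        rng = np.random.default_rng(13)
        th = rng.uniform(0, 360, 200)
        decoded = (th + rng.normal(0, 20, 200)) % 360
        a0 = iem.decoding_accuracy(decoded, th).pooled
        p0 = iem.decoding_precision(decoded, th).pooled
        rot = 73.0
        a1 = iem.decoding_accuracy((decoded + rot) % 360, (th + rot) % 360,
                                   bin_values=th).pooled
        a2 = iem.decoding_accuracy(decoded, th, bin_values=th).pooled
        assert a1 == pytest.approx(a2, abs=1e-12)
        assert np.isfinite(a0) and np.isfinite(p0)


class TestEstimatorAndCrossval:
    def test_noiseless_identity_train_equals_test(self):
        rng = np.random.default_rng(14)
        basis = iem.make_basis(exponent=6, half_angle=True)
        angles = np.arange(0, 360, 1.0)
        W = np.linalg.qr(rng.normal(size=(12, 5)))[0]
        X = (W @ basis(angles)).T
        model = iem.InvertedEncodingModel(exponent=6, half_angle=True)
        pred = model.fit(X, angles).predict(X)
        assert wrapped_abs_error(pred, angles).max() < 1e-6

    def test_filter_normalization_every_channel(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(100, 8))
        model = iem.InvertedEncodingModel().fit(X, rng.uniform(0, 360, 100))
        for i in range(5):
            assert model.filters_[i] @ model.W_[:, i] == pytest.approx(1.0)
        assert np.all((0 <= model.shrinkage_) & (model.shrinkage_ <= 1))

    def test_accuracy_decreases_with_noise(self):
        cfg = tc.SimConfig(n_blocks=1, trials_per_block=150, n_sensors=10,
                           sample_rate=64.0)
        rng = np.random.default_rng(16)
        angles = rng.uniform(0, 360, 150)
        peaks = []
        for sd in (0.0, 1.0, 4.0):
            truth = tc.GroundTruth(noise_sd=sd)
            ep = tc.synth.gen_epochs(angles, None, truth, cfg,
                                     np.random.default_rng(17))
            res = iem.crossval_iem(ep, n_folds=5, random_state=0)
            peaks.append(np.nanmax(res.accuracy))
        assert peaks[0] > peaks[1] > peaks[2]

    def test_preonset_decoding_at_chance(self, signal_epochs):
        res = iem.crossval_iem(signal_epochs, n_folds=5, random_state=1)
        pre = signal_epochs.times < 0.04
        assert np.nanmean(np.abs(res.accuracy[pre])) < 0.15
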