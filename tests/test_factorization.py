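"""Factorisation methods: constraints, optimality, recovery, conventions."""

import warnings

import numpy as np
import pytest

import emgsynergy as es


def _vaf(x, dec):
    return es.vaf(x, dec.x_hat)


class TestNMF:
    def test_exact_factorisation_on_noiseless_rank3(self, noiseless_dataset):
        _, act = noiseless_dataset
        dec = es.fit_nmf(act, 3, seed=0)
        rel_err = np.linalg.norm(act.x - dec.x_hat) / np.linalg.norm(act.x)
        assert rel_err <= 1e-3
        assert _vaf(act, dec) >= 0.999

    def test_factors_nonnegative(self, noisy_dataset):
        _, act = noisy_dataset
        dec = es.fit_nmf(act, 4, seed=1)
        assert np.all(dec.W >= 0) and np.all(dec.H >= 0)

    def test_objective_monotone_nonincreasing(self, rng):
        for _ in range(10):
            X = rng.random((6, 40))
            dec = es.fit_nmf(X, 3, seed=int(rng.integers(2**31)), restarts=1)
            h = np.asarray(dec.meta["objective_history"])
            assert np.all(np.diff(h) <= 1e-12)

    def test_vaf_nondecreasing_at_full_rank(self, noisy_dataset):
        _, act = noisy_dataset
        v_full = _vaf(act, es.fit_nmf(act, 10, seed=0))
        v_9 = _vaf(act, es.fit_nmf(act, 9, seed=0))
        assert v_full >= v_9 - 1e-6

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            es.fit_nmf(np.array([[1.0, -0.1], [0.2, 0.3]]), 1, seed=0)

    def test_k_out_of_range_rejected(self, noisy_dataset):
        _, act = noisy_dataset
        with pytest.raises(ValueError):
            es.fit_nmf(act, 11, seed=0)

    def test_quality_comparable_to_sklearn(self, noisy_dataset):
        """Independent cross-check: final objective close to scikit-learn's
        multiplicative-update NMF on the same matrix."""
        from sklearn.decomposition import NMF as SkNMF

        _, act = noisy_dataset
        dec = es.fit_nmf(act, 3, seed=0)
        sk = SkNMF(n_components=3, solver="mu", init="random", max_iter=2000,
                   random_state=0, tol=1e-6).fit(act.x)
        sk_obj = np.linalg.norm(act.x - sk.transform(act.x) @ sk.components_) ** 2
        assert dec.meta["final_objective"] <= 1.05 * sk_obj

    def test_parameter_recovery_low_noise(self):
        sims = []
        for seed in range(5):
            truth, act = es.generate_synergy_dataset(noise_sd=0.02, seed=seed)
            dec = es.fit_nmf(act, 3, seed=seed)
            _, cos = es.matched_cosine_similarity(dec.W, truth.W_true)
            sims.append(cos.mean())
        assert np.mean(sims) >= 0.9


class TestPCA:
    def test_full_rank_reconstruction_exact(self, noisy_dataset):
        _, act = noisy_dataset
        dec = es.fit_pca(act, 10)
        np.testing.assert_allclose(dec.x_hat, act.x, atol=1e-10)
        assert _vaf(act, dec) == pytest.approx(1.0, abs=1e-10)

    def test_exact_rank3_data(self, noiseless_dataset):
        _, act = noiseless_dataset
        assert _vaf(act, es.fit_pca(act, 3)) == pytest.approx(1.0, abs=1e-10)

    def test_residual_equals_tail_singular_energy(self, noisy_dataset):
        """Eckart–Young oracle: error energy = sum of discarded sigma^2."""
        _, act = noisy_dataset
        K = 3
        dec = es.fit_pca(act, K)
        s = np.linalg.svd(act.x - act.x.mean(axis=1, keepdims=True), compute_uv=False)
        np.testing.assert_allclose(
            np.sum((act.x - dec.x_hat) ** 2), np.sum(s[K:] ** 2), rtol=1e-10
        )

    def test_vaf_nondecreasing_in_K(self, noisy_dataset):
        _, act = noisy_dataset
        vafs = [_vaf(act, es.fit_pca(act, K)) for K in range(2, 7)]
        assert np.all(np.diff(vafs) >= -1e-12)

    def test_primitives_mutually_orthogonal(self, noisy_dataset):
        _, act = noisy_dataset
        dec = es.fit_pca(act, 4)
        G = dec.H @ dec.H.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-10

    def test_deterministic(self, noisy_dataset):
        _, act = noisy_dataset
        a, b = es.fit_pca(act, 3), es.fit_pca(act, 3)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)


class TestICA:
    def test_separates_laplacian_sources(self, rng):
        """Two independent Laplacian sources are recovered up to permutation
        and sign; oracle is exhaustive alignment over both permutations."""
        S = rng.laplace(size=(2, 3000))
        A = np.array([[1.0, 0.7], [0.3, 1.0]])
        dec = es.fit_ica(A @ S, 2, seed=0)
        C = np.abs(np.corrcoef(np.vstack([S, dec.H]))[:2, 2:])
        best = max(C[0, 0] + C[1, 1], C[0, 1] + C[1, 0]) / 2
        assert best >= 0.95

    def test_primitives_uncorrelated(self, noisy_dataset):
        _, act = noisy_dataset
        dec = es.fit_ica(act, 3, seed=0)
        C = np.corrcoef(dec.H)
        off = C - np.diag(np.diag(C))
        assert np.max(np.abs(off)) < 1e-6

    def test_full_rank_reconstruction(self, noisy_dataset):
        _, act = noisy_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dec = es.fit_ica(act, 10, seed=0)
        assert _vaf(act, dec) == pytest.approx(1.0, abs=1e-8)

    def test_nonconvergence_flagged_not_fatal(self, noisy_dataset):
        _, act = noisy_dataset
        with pytest.warns(RuntimeWarning):
            dec = es.fit_ica(act, 3, seed=0, max_iter=2)
        assert dec.meta["converged"] is False

    def test_logcosh_contrast_option(self, noisy_dataset):
        _, act = noisy_dataset
        dec = es.fit_ica(act, 3, seed=0, contrast="logcosh")
        assert dec.meta["contrast"] == "logcosh"
        assert _vaf(act, dec) > 0.9


class TestFA:
    def test_exact_rank3_data(self, noiseless_dataset):
        _, act = noiseless_dataset
        assert _vaf(act, es.fit_fa(act, 3)) >= 0.999

    def test_full_rank_reconstruction(self, noisy_dataset):
        _, act = noisy_dataset
        assert _vaf(act, es.fit_fa(act, 10)) == pytest.approx(1.0, abs=1e-8)

    def test_kaiser_criterion_counts_strong_factors(self, noiseless_dataset):
        _, act = noiseless_dataset
        assert es.kaiser_criterion_k(act) == 3

    def test_loadings_scaled_eigenvectors(self, noisy_dataset):
        """Before the peak-1 rescale, column norms equal sqrt(eigenvalue);
        after it, W column x H row products still reproduce the projection."""
        _, act = noisy_dataset
        dec = es.fit_fa(act, 3)
        vals = np.asarray(dec.meta["eigenvalues"])[:3]
        # x_hat is the rank-3 principal projection plus the mean
        Xc = act.x - act.x.mean(axis=1, keepdims=True)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        proj = Xc @ Vt[:3].T @ Vt[:3] + act.x.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(dec.x_hat, proj, atol=1e-8)
        assert np.all(vals[:3] > 0)


class TestSharedConventions:
    @pytest.mark.parametrize("method", es.METHODS)
    def test_primitive_rows_peak_normalised(self, noisy_dataset, method):
        _, act = noisy_dataset
        dec = es.fit_method(act, method, 3, seed=0)
        np.testing.assert_allclose(np.max(np.abs(dec.H), axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("method", ("PCA", "ICA", "FA"))
    def test_primitive_skewness_nonnegative(self, noisy_dataset, method):
        from scipy import stats as sps

        _, act = noisy_dataset
        dec = es.fit_method(act, method, 3, seed=0)
        assert np.all(sps.skew(dec.H, axis=1) >= -1e-12)

    @pytest.mark.parametrize("method", es.METHODS)
    def test_reconstruct_matches_x_hat_and_is_pure(self, noisy_dataset, method):
        _, act = noisy_dataset
        dec = es.fit_method(act, method, 3, seed=0)
        r1, r2 = es.reconstruct(dec), es.reconstruct(dec)
        np.testing.assert_array_equal(r1, r2)
        np.testing.assert_allclose(r1, dec.x_hat, atol=1e-12)
        assert r1.shape == act.x.shape

    def test_reconstruct_nmf_nonnegative(self, noisy_dataset):
        _, act = noisy_dataset
        assert np.all(es.reconstruct(es.fit_nmf(act, 3, seed=0)) >= 0)

    def test_reconstruct_shape_mismatch_rejected(self, noisy_dataset):
        _, act = noisy_dataset
        dec = es.fit_pca(act, 3)
        dec.H = dec.H[:, :100]
        dec.W = dec.W[:, :2]
        with pytest.raises(ValueError):
            es.reconstruct(dec)

    def test_unknown_method_rejected(self, noisy_dataset):
        _, act = noisy_dataset
        with pytest.raises(ValueError):
            es.fit_method(act, "SVD", 3)


class TestReconstructionErrorStats:
    def test_perfect_reconstruction_zero_residual_variance(self, noisy_dataset):
        _, act = noisy_dataset
        dec = es.fit_pca(act, 10)
        stats_ = es.reconstruction_error_stats(act, dec)
        assert stats_["var_e"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_reconstruction_mse_is_mean_square(self, rng):
        X = rng.random((3, 4))
        dec = es.SynergyDecomposition(
            W=np.zeros((3, 1)), H=np.zeros((1, 4)), method="NMF", K=1,
            x_hat=np.zeros((3, 4)),
        )
        stats_ = es.reconstruction_error_stats(X, dec)
        assert stats_["mse"] == pytest.approx(np.mean(X**2), abs=1e-15)

    def test_matches_brute_force_loop(self, rng):
        X = rng.random((3, 4))
        dec = es.fit_pca(X, 2)
        stats_ = es.reconstruction_error_stats(X, dec)
        acc = 0.0
        for i in range(3):
            for j in range(4):
                acc += (X[i, j] - dec.x_hat[i, j]) ** 2
        assert stats_["mse"] == pytest.approx(acc / 12, abs=1e-12)
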