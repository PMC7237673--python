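"""Moment summaries, ECDFs, two-sample KS and the all-pairs comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import emgsynergy as es
from emgsynergy.distribution_metrics import EcdfSample


def _brute_force_ks(a, b, n_grid=10**5):
    """Dense-grid supremum of |F_a - F_b| (oracle)."""
    lo = min(a.min(), b.min()) - 1.0
    hi = max(a.max(), b.max()) + 1.0
    grid = np.concatenate([np.linspace(lo, hi, n_grid), a, b])
    Fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    Fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return np.max(np.abs(Fa - Fb))


class TestSummarise:
    def test_gaussian_and_laplacian_reference_values(self):
        rng = np.random.default_rng(1)
        g = es.summarise_distribution(rng.normal(size=10**6))
        assert g.excess_kurtosis == pytest.approx(0.0, abs=0.05)
        l = es.summarise_distribution(rng.laplace(size=10**6))
        assert l.excess_kurtosis == pytest.approx(3.0, abs=0.1)

    def test_symmetrised_sample_has_zero_skewness(self, rng):
        x = rng.gamma(2.0, size=500)
        sym = np.concatenate([x, 2 * x.mean() - x])
        assert es.summarise_distribution(sym).skewness == pytest.approx(0.0, abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            es.summarise_distribution([1.0, 2.0, 3.0])


class TestGaussianPdfModel:
    def test_standard_normal_density_at_mean(self):
        s = es.DistributionSummary(0.0, 0.0, 0.0, 1.0, 100)
        assert es.gaussian_pdf_model(s, np.array([0.0]))[0] == pytest.approx(0.3989, abs=5e-5)

    def test_integrates_to_one(self):
        s = es.DistributionSummary(0.0, 0.0, 0.3, 2.0, 100)
        grid = np.linspace(-20, 20, 4001)
        assert np.trapezoid(es.gaussian_pdf_model(s, grid), grid) == pytest.approx(1.0, abs=1e-3)

    def test_location_shift_translates_curve(self):
        grid = np.linspace(-5, 5, 101)
        a = es.gaussian_pdf_model(es.DistributionSummary(0, 0, 0.0, 1.0, 10), grid)
        b = es.gaussian_pdf_model(es.DistributionSummary(0, 0, 1.5, 1.0, 10), grid + 1.5)
        np.testing.assert_allclose(a, b, atol=1e-15)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            es.gaussian_pdf_model(es.DistributionSummary(0, 0, 0.0, 0.0, 10), np.zeros(3))


class TestEcdf:
    def test_counting(self):
        F = es.ecdf([1.0, 2.0, 3.0])
        assert F.evaluate(2.0) == pytest.approx(2 / 3)
        assert F.evaluate(0.5) == 0.0
        assert F.evaluate(3.0) == 1.0
        assert F.evaluate(99.0) == 1.0

    def test_tied_mass(self):
        assert es.ecdf([1.0, 1.0, 2.0]).evaluate(1.0) == pytest.approx(2 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            es.ecdf([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_step_function_properties(self, values):
        F = es.ecdf(values)
        grid = np.linspace(min(values) - 1, max(values) + 1, 200)
        y = F.evaluate(grid)
        assert np.all(np.diff(y) >= 0)  # non-decreasing
        assert np.all((y >= 0) & (y <= 1))
        assert F.evaluate(np.inf) == 1.0 and F.evaluate(-np.inf) == 0.0


class TestKsTwoSample:
    def test_identical_samples(self, rng):
        a = rng.normal(size=50)
        r = es.ks_two_sample(a, a.copy())
        assert r["D"] == 0.0 and r["p"] == 1.0

    def test_disjoint_supports(self):
        r = es.ks_two_sample([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert r["D"] == 1.0

    def test_matches_grid_oracle_and_scipy(self, rng):
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(20, 300)))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), size=int(rng.integers(20, 300)))
            r = es.ks_two_sample(a, b)
            assert r["D"] == pytest.approx(_brute_force_ks(a, b), abs=1e-12)
            assert r["D"] == pytest.approx(stats.ks_2samp(a, b).statistic, abs=1e-12)

    def test_affine_invariance(self, rng):
        a, b = rng.normal(size=120), rng.normal(0.4, 1.3, size=90)
        r1 = es.ks_two_sample(a, b)
        r2 = es.ks_two_sample(2.5 * a - 1.0, 2.5 * b - 1.0)
        assert r1["D"] == pytest.approx(r2["D"], abs=1e-15)
        assert r1["p"] == pytest.approx(r2["p"], abs=1e-15)

    def test_accepts_ecdf_objects(self, rng):
        a, b = rng.normal(size=40), rng.normal(size=60)
        r1 = es.ks_two_sample(a, b)
        r2 = es.ks_two_sample(EcdfSample(a), EcdfSample(b))
        assert r1 == r2


class TestComparePrimitivesToActivations:
    def _fake_dec(self, H):
        H = np.asarray(H, dtype=float)
        return es.SynergyDecomposition(
            W=np.zeros((5, H.shape[0])), H=H, method="NMF", K=H.shape[0],
            x_hat=np.zeros((5, H.shape[1])),
        )

    def test_copied_rows_agree_perfectly(self, rng):
        X = rng.random((5, 200))
        comp = es.compare_primitives_to_activations(
            X, self._fake_dec(X[:2].copy()), primitive_prep="raw"
        )
        assert comp.D_lk[0, 0] == 0.0 and comp.D_lk[1, 1] == 0.0
        assert np.all(comp.p_lk[[0, 1], [0, 1]] == 1.0)

    def test_agreement_boundaries(self, rng):
        X = rng.random((5, 200))
        perfect = es.compare_primitives_to_activations(
            X, self._fake_dec(np.vstack([X[0], X[1]])), primitive_prep="raw"
        )
        # matched pairs agree; the same primitives against muscles 2-4 may not
        assert perfect.agreement_pct >= 100.0 * 2 / 10
        hostile = es.compare_primitives_to_activations(
            X, self._fake_dec(np.vstack([X[0] + 10, X[1] - 10])), primitive_prep="raw"
        )
        assert hostile.agreement_pct == 0.0
        assert hostile.D_max == 1.0

    def test_dmax_is_brute_force_max_over_pairs(self, rng):
        X = rng.random((5, 150))
        H = rng.random((2, 150))
        comp = es.compare_primitives_to_activations(X, self._fake_dec(H), primitive_prep="raw")
        brute = max(
            _brute_force_ks(X[l], H[k]) for l in range(5) for k in range(2)
        )
        assert comp.D_max == pytest.approx(brute, abs=1e-12)
        assert comp.D_max == comp.D_lk.max() == comp.D_k.max()

    def test_dmax_invariant_to_relabelling(self, rng):
        X = rng.random((5, 100))
        H = rng.random((2, 100))
        c1 = es.compare_primitives_to_activations(X, self._fake_dec(H))
        c2 = es.compare_primitives_to_activations(X[::-1].copy(), self._fake_dec(H[::-1].copy()))
        assert c1.D_max == pytest.approx(c2.D_max, abs=1e-15)
        assert c1.agreement_pct == pytest.approx(c2.agreement_pct, abs=1e-12)

    def test_min_reduction_option(self, rng):
        X = rng.random((5, 100))
        H = rng.random((2, 100))
        c = es.compare_primitives_to_activations(X, self._fake_dec(H), reduction="min")
        np.testing.assert_allclose(c.D_k, c.D_lk.min(axis=0))

    def test_too_many_primitives_rejected(self, rng):
        X = rng.random((3, 50))
        dec = self._fake_dec(rng.random((3, 50)))
        with pytest.raises(ValueError):
            es.compare_primitives_to_activations(X, dec)

    def test_minmax_prep_maps_to_unit_interval(self, noisy_dataset):
        _, act = noisy_dataset
        dec = es.fit_pca(act, 3)  # PCA primitives are signed
        comp = es.compare_primitives_to_activations(act, dec)
        assert np.all(comp.D_lk <= 1.0) and np.all(comp.D_lk >= 0.0)
        assert 0.0 <= comp.agreement_pct <= 100.0
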