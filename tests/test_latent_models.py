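"""PLS/KPLS cores: NIPALS orthogonality, OLS limit, kernel equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsrr import choose_sigma, fit_kpls, fit_pls, rbf_kernel
from qsrr.latent_models import ModelError, _rbf_gram


class TestRBFKernel:
    def test_identical_points(self, rng):
        x = rng.normal(size=6)
        assert rbf_kernel(x, x, 2.0) == 1.0

    def test_hand_computed_value(self):
        v = rbf_kernel(np.zeros(2), np.ones(2), 1.0)
        assert v == pytest.approx(np.exp(-1.0), abs=1e-9)   # d2 = 2, exponent -2/2

    def test_monotone_in_sigma(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        vals = [rbf_kernel(a, b, s) for s in (0.5, 1, 2, 5, 50)]
        assert all(x < y for x, y in zip(vals, vals[1:]))
        assert vals[-1] > 0.99

    def test_invalid_sigma(self):
        with pytest.raises(ModelError):
            rbf_kernel(np.zeros(2), np.ones(2), 0.0)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 2**16), n=st.integers(3, 15))
    def test_gram_matrix_psd(self, seed, n):
        X = np.random.default_rng(seed).normal(size=(n, 4))
        K = _rbf_gram(X, X, 1.3)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestPLS:
    def test_noiseless_full_rank_r2_one(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + 4.0
        m = fit_pls(X, y, 3)
        ss_res = np.sum((y - m.predict(X)) ** 2)
        assert ss_res / np.sum((y - y.mean()) ** 2) < 1e-8

    def test_equals_ols_at_full_rank(self, rng):
        for _ in range(5):
            X = rng.normal(size=(30, 4))
            y = X @ rng.normal(size=4) + rng.normal(size=30) * 0.3
            m = fit_pls(X, y, 4)
            A = np.hstack([np.ones((30, 1)), X])
            beta = np.linalg.lstsq(A, y, rcond=None)[0]
            np.testing.assert_allclose(m.predict(X), A @ beta, atol=1e-6)

    def test_single_lv_weight_tracks_covariance(self, rng):
        X = rng.normal(size=(100, 5))
        y = 5.0 * X[:, 2] + rng.normal(size=100) * 0.1
        m = fit_pls(X, y, 1)
        cov = np.abs(m.scaler.transform(X).T @ (y - y.mean()))
        assert np.argmax(np.abs(m.x_weights[:, 0])) == np.argmax(cov) == 2

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(40, 8))
        y = rng.normal(size=40)
        m = fit_pls(X, y, 5)
        G = m.scores.T @ m.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_training_r2_nondecreasing_in_lv(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        sse = []
        for lv in range(1, 6):
            m = fit_pls(X, y, lv)
            sse.append(np.sum((y - m.predict(X)) ** 2))
        assert all(a >= b - 1e-10 for a, b in zip(sse, sse[1:]))

    def test_matches_sklearn_pls(self, rng):
        # independent NIPALS implementation as an oracle at partial rank
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(40, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=40)
        for lv in (1, 2, 4):
            ours = fit_pls(X, y, lv)
            ref = PLSRegression(n_components=lv, scale=True).fit(X, y)
            np.testing.assert_allclose(
                ours.predict(X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_zero_lv_predicts_mean(self, rng):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        m = fit_pls(X, y, 0)
        np.testing.assert_allclose(m.predict(X), y.mean(), atol=1e-12)

    def test_coefficients_in_original_units(self, rng):
        X = rng.normal(size=(25, 3)) * [2.0, 5.0, 0.3] + [1.0, -4.0, 10.0]
        y = X @ np.array([0.5, -1.0, 2.0]) + 3.0
        m = fit_pls(X, y, 3)
        np.testing.assert_allclose(
            m.intercept + X @ m.coefficients, m.predict(X), atol=1e-8
        )

    def test_rank_collapse_reports_achievable(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x + 1e-14, x - 3])   # rank deficient
        y = x * 2.0
        with pytest.raises(ModelError, match="achievable rank"):
            fit_pls(X, y, 3)

    def test_predict_rejects_wrong_width(self, rng):
        m = fit_pls(rng.normal(size=(10, 3)), rng.normal(size=10), 2)
        with pytest.raises(ModelError, match="descriptor columns"):
            m.predict(rng.normal(size=(4, 5)))


class TestKPLS:
    @settings(deadline=None, max_examples=10)
    @given(seed=st.integers(0, 2**16))
    def test_linear_kernel_equals_pls(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(25, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=25) * 0.2
        for lv in (1, 3):
            mk = fit_kpls(X, y, None, lv, kernel="linear")
            mp = fit_pls(X, y, lv)
            Xnew = rng.normal(size=(8, 4))
            np.testing.assert_allclose(mk.predict(Xnew), mp.predict(Xnew), atol=1e-6)

    def test_training_prediction_matches_fitted(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.sin(X[:, 0]) + rng.normal(size=30) * 0.05
        m = fit_kpls(X, y, 1.5, 4)
        np.testing.assert_allclose(m.predict(X), m.fitted, atol=1e-10)

    def test_interpolates_noiseless_at_full_rank(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.sin(X[:, 0]) + np.cos(X[:, 1])
        m = fit_kpls(X, y, 2.0, 19)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-6)

    def test_nonlinear_surface_fit(self, rng):
        X = rng.normal(size=(60, 1))
        y = np.sin(2.0 * X[:, 0])
        sigma = choose_sigma(X, y, n_lv=3, seed=0)
        m = fit_kpls(X, y, sigma, 3)
        r2 = 1 - np.sum((y - m.predict(X)) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 >= 0.99

    def test_training_r2_nondecreasing_in_lv(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        sse = [
            np.sum((y - fit_kpls(X, y, 2.0, lv).fitted) ** 2) for lv in range(1, 8)
        ]
        assert all(a >= b - 1e-10 for a, b in zip(sse, sse[1:]))


class TestChooseSigma:
    def test_single_grid_point(self, rng):
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        from scipy.spatial.distance import pdist

        got = choose_sigma(X, y, grid=(2.0,), n_lv=2, seed=0)
        # exactly the single candidate: 2 x median scaled distance
        assert got == pytest.approx(
            2.0 * np.median(pdist((X - X.mean(0)) / X.std(0, ddof=1)))
        )

    def test_reproducible(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.sin(X[:, 0]) + rng.normal(size=40) * 0.05
        a = choose_sigma(X, y, n_lv=3, seed=5)
        b = choose_sigma(X, y, n_lv=3, seed=5)
        assert a == b

    def test_degenerate_distances_rejected(self):
        with pytest.raises(ModelError, match="identical"):
            choose_sigma(np.ones((10, 2)) * 5, np.arange(10.0))
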