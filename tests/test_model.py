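import numpy as np
import pytest

from irspec_calib import (
    BandSpec,
    generate_spectra,
    hybrid_fit,
    lssvm_fit,
    nipals_pls_fit,
    pls_transform,
    rbf_kernel,
    tune_hyperparameters,
)
from irspec_calib.exceptions import (
    ConfigError,
    IllConditionedError,
    RankError,
    ShapeError,
)
from irspec_calib.model import lssvm_predict, median_sq_distance
from irspec_calib.validation import press

from conftest import tiny_config


class TestNipalsPls:
    def test_single_latent_factor_exact(self, rng):
        w = rng.normal(size=30)
        w /= np.linalg.norm(w)
        t = rng.normal(size=20)
        X = np.outer(t, w)
        y = t.copy()
        pls = nipals_pls_fit(X, y, 1)
        np.testing.assert_allclose(pls.predict(X), y, atol=1e-10)

    @pytest.mark.parametrize("A", [1, 2, 3, 5])
    def test_matches_sklearn_oracle(self, A, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(20, 50))
        y = rng.normal(size=20)
        ours = nipals_pls_fit(X, y, A)
        ref = PLSRegression(n_components=A, scale=False).fit(X, y)
        np.testing.assert_allclose(
            ours.predict(X), ref.predict(X).ravel(), atol=1e-8
        )
        T_ours = pls_transform(ours, X)
        T_ref = ref.transform(X)
        for a in range(A):  # per-component sign is a free convention
            s = np.sign(T_ours[0, a] * T_ref[0, a]) or 1.0
            np.testing.assert_allclose(T_ours[:, a], s * T_ref[:, a], atol=1e-8)

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        pls = nipals_pls_fit(X, y, 4)
        Xd = np.column_stack([X, np.ones(10)])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        np.testing.assert_allclose(pls.predict(X), Xd @ beta, atol=1e-8)

    def test_rank_error_reports_achievable(self, rng):
        t = rng.normal(size=15)
        X = np.outer(t, rng.normal(size=8))  # rank-1 X
        with pytest.raises(RankError) as exc:
            nipals_pls_fit(X, t, 3)
        assert exc.value.achievable == 1

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(25, 40))
        y = rng.normal(size=25)
        pls = nipals_pls_fit(X, y, 5)
        T = pls_transform(pls, X)
        G = T.T @ T
        norms = np.sqrt(np.diag(G))
        off = G / np.outer(norms, norms) - np.eye(5)
        assert np.max(np.abs(off)) < 1e-8

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ConfigError):
            nipals_pls_fit(rng.normal(size=(8, 5)), np.ones(8), 1)

    def test_a_out_of_range(self, rng):
        with pytest.raises(ConfigError):
            nipals_pls_fit(rng.normal(size=(5, 8)), rng.normal(size=5), 5)


class TestPlsTransform:
    @pytest.fixture
    def fitted(self, rng):
        X = rng.normal(size=(15, 12))
        y = rng.normal(size=15)
        return X, nipals_pls_fit(X, y, 3)

    def test_reproduces_training_scores(self, fitted):
        X, pls = fitted
        # recompute training scores by running the deflation forward
        Xc = X - pls.x_mean
        T_ref = np.empty((15, 3))
        for a in range(3):
            T_ref[:, a] = Xc @ pls.weights[:, a]
            Xc = Xc - np.outer(T_ref[:, a], pls.loadings[:, a])
        np.testing.assert_allclose(pls_transform(pls, X), T_ref, atol=1e-10)

    def test_mean_row_maps_to_zero(self, fitted):
        _, pls = fitted
        np.testing.assert_allclose(
            pls_transform(pls, pls.x_mean), np.zeros(3), atol=1e-12
        )

    def test_linearity_about_center(self, fitted, rng):
        X, pls = fitted
        x = rng.normal(size=12)
        np.testing.assert_allclose(
            pls_transform(pls, 2 * x - pls.x_mean),
            2 * pls_transform(pls, x),
            atol=1e-10,
        )

    def test_dimension_mismatch(self, fitted):
        _, pls = fitted
        with pytest.raises(ShapeError):
            pls_transform(pls, np.zeros((3, 5)))


class TestRbfKernel:
    def test_self_similarity_is_one(self, rng):
        t = rng.normal(size=4)
        assert rbf_kernel(t, t, 2.0) == pytest.approx(1.0)

    def test_closed_form_at_two_sigma2(self):
        # ||t1 - t2||^2 = 2 sigma2 -> exp(-1)
        assert rbf_kernel([0.0], [2.0], 2.0) == pytest.approx(np.exp(-1))

    def test_symmetry(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3)
        assert rbf_kernel(a, b, 0.7) == pytest.approx(rbf_kernel(b, a, 0.7))

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ConfigError):
            rbf_kernel([0.0], [1.0], 0.0)


class TestLssvm:
    def test_constant_y_gives_zero_alphas(self, rng):
        T = rng.normal(size=(6, 2))
        m = lssvm_fit(T, np.full(6, 3.5), gamma=10.0, sigma2=1.0)
        np.testing.assert_allclose(m.alpha, 0.0, atol=1e-10)
        assert m.b == pytest.approx(3.5)
        np.testing.assert_allclose(m.predict(T), 3.5, atol=1e-10)

    def test_two_point_closed_form(self):
        # t = {0, 1}, y = {0, 1}, gamma = 1, sigma2 = 0.5:
        # k = exp(-1); alpha = -/+ 1/(2 (2 - k)); b = 1/2
        m = lssvm_fit(np.array([[0.0], [1.0]]), np.array([0.0, 1.0]),
                      gamma=1.0, sigma2=0.5)
        k = np.exp(-1.0)
        a = 1.0 / (2.0 * (2.0 - k))
        np.testing.assert_allclose(m.alpha, [-a, a], atol=1e-10)
        assert m.b == pytest.approx(0.5, abs=1e-10)

    def test_kkt_identities(self, rng):
        T = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        gamma = 37.0
        m = lssvm_fit(T, y, gamma=gamma, sigma2=1.3)
        assert abs(m.alpha.sum()) < 1e-8 * (np.abs(m.alpha).max() + 1)
        resid = y - m.predict(T)
        np.testing.assert_allclose(m.alpha, gamma * resid, atol=1e-8)

    def test_interpolation_limit(self, rng):
        T = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        m = lssvm_fit(T, y, gamma=1e8, sigma2=2.0)
        np.testing.assert_allclose(m.predict(T), y, atol=1e-4)

    def test_ill_conditioned_detected(self):
        T = np.array([[0.0], [0.0], [1.0]])  # exact duplicates + huge gamma
        with pytest.raises(IllConditionedError):
            lssvm_fit(T, np.array([0.0, 1.0, 2.0]), gamma=1e18, sigma2=1.0)

    def test_monotone_ridge_limit(self, rng):
        T = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        prev = np.inf
        for gamma in (1e-2, 1e-1, 1e0, 1e1, 1e2, 1e3):
            m = lssvm_fit(T, y, gamma=gamma, sigma2=1.0)
            p = press(y, m.predict(T))
            assert p <= prev + 1e-9
            prev = p


class TestHybrid:
    def test_noise_free_one_band_r2(self):
        cfg = tiny_config(
            interferent_bands=[],
            background_bands=[],
            baseline_offset_sd=0.0,
            scatter_sd=0.0,
            noise_sd=0.0,
            analyte_bands=[BandSpec(1200.0, 60.0, 0.02)],
        )
        m, truth = generate_spectra(cfg)
        X, y = m.intensities, truth.concentrations.values
        model = hybrid_fit(X, y, 1, gamma=1e4, sigma2=median_sq_distance(
            pls_transform(nipals_pls_fit(X, y, 1), X)))
        pred = model.predict(X)
        ss = np.sum((y - y.mean()) ** 2)
        assert 1 - np.sum((y - pred) ** 2) / ss > 0.999

    def test_large_gamma_sigma2_degenerates_to_linear_pls(self, rng):
        # on linear data, an extremely wide + barely-regularized RBF behaves
        # like the linear PLS regression on the same scores
        n, p = 40, 25
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = X @ beta
        pls = nipals_pls_fit(X, y, 3)
        lin = pls.predict(X)
        hyb = hybrid_fit(X, y, 3, gamma=1e9, sigma2=1e7 * median_sq_distance(
            pls_transform(pls, X)))
        span = np.ptp(y)
        assert np.max(np.abs(hyb.predict(X) - lin)) < 0.01 * span

    def test_predict_composition_consistency(self, rng):
        X = rng.normal(size=(18, 10))
        y = rng.normal(size=18)
        model = hybrid_fit(X, y, 2, gamma=50.0, sigma2=3.0)
        T = pls_transform(model.pls, X)
        np.testing.assert_allclose(
            model.predict(X), lssvm_predict(model.lssvm, T), atol=1e-12
        )

    def test_oracle_equivalence_direct_solver(self, rng):
        # independent route: scalar-kernel loops + generic numpy solve
        X = rng.normal(size=(30, 15))
        y = rng.normal(size=30)
        A, gamma, sigma2 = 3, 25.0, 4.0
        model = hybrid_fit(X, y, A, gamma, sigma2)
        T = pls_transform(model.pls, X)
        n = len(y)
        M = np.zeros((n + 1, n + 1))
        M[0, 1:] = M[1:, 0] = 1.0
        for i in range(n):
            for j in range(n):
                M[1 + i, 1 + j] = rbf_kernel(T[i], T[j], sigma2)
            M[1 + i, 1 + i] += 1.0 / gamma
        sol = np.linalg.solve(M, np.concatenate(([0.0], y)))
        b, alpha = sol[0], sol[1:]
        X_new = rng.normal(size=(5, 15))
        T_new = pls_transform(model.pls, X_new)
        ref = np.array(
            [
                sum(alpha[i] * rbf_kernel(t, T[i], sigma2) for i in range(n)) + b
                for t in T_new
            ]
        )
        np.testing.assert_allclose(model.predict(X_new), ref, atol=1e-8)


class TestTuneHyperparameters:
    def test_selected_pair_is_loo_press_argmin(self, rng):
        from irspec_calib.validation import loo_cv

        X = rng.normal(size=(15, 8))
        y = X @ rng.normal(size=8) + 0.1 * rng.normal(size=15)
        A = 2
        gammas, sigma2s = [1.0, 100.0], [0.5, 5.0]
        got = tune_hyperparameters(X, y, A, gammas, sigma2s)
        table = {
            (g, s): loo_cv(X, y, A, g, s).press for g in gammas for s in sigma2s
        }
        best = min(table.values())
        assert table[got] == pytest.approx(best)
        # tie rule: smallest gamma then largest sigma2 among the minima
        winners = [k for k, v in table.items() if v <= best * (1 + 1e-12)]
        assert got == min(winners, key=lambda k: (k[0], -k[1]))

    def test_single_point_grids(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        assert tune_hyperparameters(X, y, 2, [7.0], [2.5]) == (7.0, 2.5)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ConfigError):
            tune_hyperparameters(
                rng.normal(size=(10, 6)), rng.normal(size=10), 2, [], [1.0]
            )
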