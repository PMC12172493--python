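import numpy as np
import pytest

from medimix import (
    DebiasedLassoLMM,
    build_covariance_proxy,
    debias,
    lambda_grid,
    lasso_fixed_effects,
    nodewise_score,
    select_a,
    select_lambda,
    whiten,
)
from medimix.hdlmm import cluster_kfold, eq_objective
from medimix.synthetic import generate_lmm_regression


def _whitened(rng, n=10, m_range=(3, 6), p=6, a=1.0, psi=1.0, sigma=1.0):
    m = rng.integers(*m_range, n)
    groups = np.repeat(np.arange(n), m)
    N = int(m.sum())
    X = rng.normal(size=(N, p))
    beta = np.zeros(p)
    beta[:2] = [1.5, -1.0]
    y = X @ beta + np.repeat(rng.normal(0, np.sqrt(psi), n), m) + rng.normal(0, sigma, N)
    proxy = build_covariance_proxy(m, a)
    return whiten(X, y, proxy, groups), beta


class TestCovarianceProxy:
    def test_a_zero_identity(self):
        pr = build_covariance_proxy([2, 3], 0.0)
        assert np.allclose(pr.block(0), np.eye(2))
        assert pr.trace_inv == pytest.approx(5.0)

    def test_compound_symmetry_example(self):
        pr = build_covariance_proxy([3], 2.0)
        assert np.allclose(pr.block(0), 2 * np.ones((3, 3)) + np.eye(3))
        assert pr.trace_inv == pytest.approx(1 / 7 + 2, abs=1e-12)

    @pytest.mark.parametrize("a,m", [(0.5, 2), (1.0, 5), (8.0, 24)])
    def test_trace_closed_form(self, a, m):
        pr = build_covariance_proxy([m], a)
        assert pr.trace_inv == pytest.approx(
            np.trace(np.linalg.inv(pr.block(0))), rel=1e-12
        )
        assert pr.trace_inv == pytest.approx(1 / (1 + a * m) + (m - 1), rel=1e-12)

    def test_inverse_sqrt_reconstruction(self):
        pr = build_covariance_proxy([4], 1.7)
        S = pr.inv_sqrt_block(0)
        assert np.abs(S @ pr.block(0) @ S - np.eye(4)).max() < 1e-10

    def test_invalid_a(self):
        with pytest.raises(ValueError):
            build_covariance_proxy([3], np.nan)
        with pytest.raises(ValueError):
            build_covariance_proxy([3], -1.0)


class TestWhiten:
    def test_a_zero_is_identity(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        d = whiten(X, y, build_covariance_proxy([2, 3], 0.0))
        assert np.allclose(d.Xa, X) and np.allclose(d.ya, y)

    def test_linearity(self, rng):
        X = rng.normal(size=(7, 2))
        y = rng.normal(size=7)
        pr = build_covariance_proxy([3, 4], 2.0)
        d1 = whiten(X, y, pr)
        d2 = whiten(X, 3.5 * y, pr)
        assert np.allclose(d2.ya, 3.5 * d1.ya, atol=1e-12)

    def test_quadratic_form(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        pr = build_covariance_proxy([2, 3], 1.5)
        d = whiten(X, y, pr)
        Sinv = np.zeros((5, 5))
        Sinv[:2, :2] = pr.inv_block(0)
        Sinv[2:, 2:] = pr.inv_block(1)
        assert d.ya @ d.ya == pytest.approx(y @ Sinv @ y, abs=1e-8)

    def test_size_mismatch(self, rng):
        with pytest.raises(ValueError, match="row count"):
            whiten(rng.normal(size=(4, 2)), rng.normal(size=4),
                   build_covariance_proxy([2, 3], 1.0))


class TestLasso:
    def test_orthonormal_soft_threshold(self):
        # Xa = I2 (Tr = 2), ya = (3, 0.5), lambda = 1: threshold at
        # lambda * Tr = 2 gives (1, 0)
        d = whiten(np.eye(2), np.array([3.0, 0.5]), build_covariance_proxy([1, 1], 0.0))
        fit = lasso_fixed_effects(d, 1.0)
        assert np.allclose(fit.beta, [1.0, 0.0], atol=1e-8)

    def test_lambda_max_kkt(self, rng):
        d, _ = _whitened(rng)
        lam_max = np.abs(d.Xa.T @ d.ya).max() / d.trace_inv
        fit = lasso_fixed_effects(d, lam_max * 1.0001)
        assert np.allclose(fit.beta, 0.0, atol=1e-10)

    def test_lambda_zero_least_squares(self, rng):
        d, _ = _whitened(rng)
        fit = lasso_fixed_effects(d, 0.0)
        ls, *_ = np.linalg.lstsq(d.Xa, d.ya, rcond=None)
        assert np.allclose(fit.beta, ls, atol=1e-6)

    def test_unpenalized_intercept_profiling_is_exact(self, rng):
        # KKT: |Xa_pen' r| / Tr <= lam (+ equality on the support), and the
        # intercept column is orthogonal to the residual
        d, _ = _whitened(rng, p=4)
        Xd = np.column_stack([np.ones(len(d.ya)), d.Xa])
        d2 = whiten(Xd, d.ya, d.proxy)
        lam = 0.05
        fit = lasso_fixed_effects(d2, lam, unpenalized=(0,))
        r = d2.ya - d2.Xa @ fit.beta
        grad = np.abs(d2.Xa[:, 1:].T @ r) / d2.trace_inv
        assert grad.max() <= lam * (1 + 1e-6)
        on = np.abs(fit.beta[1:]) > 1e-10
        assert np.allclose(grad[on], lam, atol=1e-6)
        assert abs(d2.Xa[:, 0] @ r) < 1e-8

    def test_objective_decreases_vs_perturbation(self, rng):
        d, _ = _whitened(rng)
        fit = lasso_fixed_effects(d, 0.1)
        base = eq_objective(fit.beta, d, 0.1)
        assert base == pytest.approx(fit.objective, rel=1e-10)
        for _ in range(5):
            assert eq_objective(fit.beta + 0.01 * rng.normal(size=len(fit.beta)),
                                d, 0.1) >= base


class TestTuningSelection:
    def test_lambda_grid_formula(self):
        g = lambda_grid(10, 40)
        base = np.sqrt(2 * np.log(10) / 40)
        assert g[0] == pytest.approx(2.0 * base)
        assert g[-1] == pytest.approx(0.1 * base)
        assert len(g) == 20 and np.all(np.diff(g) < 0)

    def test_lambda_grid_fallback_p1(self):
        g = lambda_grid(1, 40)
        assert np.isfinite(g).all() and (g > 0).all()

    def test_single_candidate_a(self, rng):
        d, _ = _whitened(rng)
        assert select_a(d.X, d.y, d.groups, candidate_as=[0.7]) == 0.7

    def test_negative_candidate_errors(self, rng):
        d, _ = _whitened(rng)
        with pytest.raises(ValueError, match=">= 0"):
            select_a(d.X, d.y, d.groups, candidate_as=[-1.0, 1.0])

    def test_single_lambda_grid(self, rng):
        d, _ = _whitened(rng)
        lam = select_lambda(d, multipliers=[0.5])
        assert lam == pytest.approx(0.5 * np.sqrt(2 * np.log(6) / len(d.ya)))

    def test_pure_noise_selects_sparse_end(self):
        # fixed-seed sanity: with no signal, CV lands at the sparse (large
        # lambda) end of the grid where the fit is exactly null
        rng = np.random.default_rng(1)
        n, m, p = 30, 4, 15
        groups = np.repeat(np.arange(n), m)
        X = rng.normal(size=(n * m, p))
        y = rng.normal(size=n * m)
        d = whiten(X, y, build_covariance_proxy(np.full(n, m), 0.5), groups)
        lam = select_lambda(d, rng=0)
        grid = lambda_grid(p, n * m)
        assert lam >= 0.75 * grid[0]

    def test_cv_winner_is_exhaustive_argmin(self, rng):
        # select_a returns the candidate whose (min over lambda) CV error,
        # on identical fold splits, is smallest
        from medimix.hdlmm import _cv_sse_over_lambda

        d, _ = _whitened(rng, n=12, a=0.0, psi=4.0)
        cands = [0.0, 4.0]
        picked = select_a(d.X, d.y, d.groups, candidate_as=cands, rng=99)
        folds = cluster_kfold(d.groups, 5, np.random.default_rng(99))
        lams = lambda_grid(d.X.shape[1], len(d.y))
        scores = [
            _cv_sse_over_lambda(d.X, d.y, d.groups, a, lams, folds).min()
            for a in cands
        ]
        assert picked == cands[int(np.argmin(scores))]

    def test_fewer_clusters_than_folds(self):
        with pytest.raises(ValueError, match="folds"):
            cluster_kfold(np.array([0, 0, 1, 1]), 5, np.random.default_rng(0))


class TestNodewise:
    def test_orthogonal_columns(self):
        Xa = np.kron(np.eye(3), np.ones(2)[:, None]).reshape(6, 3) * 0
        Xa = np.zeros((6, 3))
        Xa[:2, 0] = [1, -1]
        Xa[2:4, 1] = [1, -1]
        Xa[4:, 2] = [1, -1]
        d = whiten(Xa, np.zeros(6), build_covariance_proxy([2, 2, 2], 0.0))
        sc = nodewise_score(d, 0, lambda_j=0.01)
        assert np.allclose(sc.kappa, 0.0, atol=1e-10)
        assert np.allclose(sc.w, Xa[:, 0], atol=1e-10)

    def test_p_equal_one(self, rng):
        X = rng.normal(size=(6, 1))
        d = whiten(X, np.zeros(6), build_covariance_proxy([3, 3], 0.0))
        sc = nodewise_score(d, 0)
        assert np.allclose(sc.w, d.Xa[:, 0])

    def test_duplicated_column_degenerate(self, rng):
        x = rng.normal(size=6)
        X = np.column_stack([x, x])
        d = whiten(X, np.zeros(6), build_covariance_proxy([3, 3], 0.0))
        with pytest.raises(ValueError, match="degenerate correction score"):
            nodewise_score(d, 0, lambda_j=0.0)


class TestDebias:
    def test_zero_residual(self, rng):
        d, _ = _whitened(rng, p=3)
        beta, *_ = np.linalg.lstsq(d.Xa, d.ya, rcond=None)
        d.ya = d.Xa @ beta  # make the residual exactly zero
        fit = lasso_fixed_effects(d, 0.0)
        scores = [nodewise_score(d, j, lambda_j=0.05) for j in range(3)]
        db = debias(fit, scores, d)
        assert np.allclose(db.beta_db, fit.beta, atol=1e-8)
        assert np.allclose(db.variance, 0.0, atol=1e-12)

    def test_identity_design_recovers_ya(self):
        d = whiten(np.eye(4), np.array([2.0, -1.0, 0.5, 3.0]),
                   build_covariance_proxy([1] * 4, 0.0))
        fit = lasso_fixed_effects(d, 0.5)
        scores = [nodewise_score(d, j, lambda_j=0.01) for j in range(4)]
        db = debias(fit, scores, d)
        assert np.allclose(db.beta_db, d.ya, atol=1e-8)

    def test_variance_brute_force_three_clusters(self, rng):
        d, _ = _whitened(rng, n=3, m_range=(3, 5), p=2)
        fit = lasso_fixed_effects(d, 0.05)
        sc = nodewise_score(d, 0, lambda_j=0.05)
        db = debias(fit, [sc], d)
        resid = d.ya - d.Xa @ fit.beta
        num, off = 0.0, 0
        for m_i in d.proxy.cluster_sizes:
            num += float(sc.w[off:off + m_i] @ resid[off:off + m_i]) ** 2
            off += m_i
        expected = num / float(sc.w @ d.Xa[:, 0]) ** 2
        assert db.variance[0] == pytest.approx(expected, rel=1e-12)


class TestEstimator:
    def test_within_cluster_permutation_invariance(self, rng):
        X, y, groups, _ = generate_lmm_regression(n=10, cluster_size_range=(3, 5),
                                                  p=8, s=2, seed=4)
        est1 = DebiasedLassoLMM(a=1.0, random_state=0).fit(X, y, groups)
        order = np.concatenate(
            [np.random.default_rng(1).permutation(np.flatnonzero(groups == gid))
             for gid in np.unique(groups)]
        )
        est2 = DebiasedLassoLMM(a=1.0, random_state=0).fit(X[order], y[order],
                                                           groups[order])
        assert np.allclose(est1.coef_db_, est2.coef_db_, atol=1e-10)
        assert est1.lambda_ == est2.lambda_

    def test_sklearn_params_round_trip(self):
        est = DebiasedLassoLMM(a=2.0, cv=3)
        est2 = est.set_params(**est.get_params())
        assert est2.get_params()["a"] == 2.0 and est2.get_params()["cv"] == 3

    def test_predict_uses_lasso_coefficients(self, rng):
        X, y, groups, _ = generate_lmm_regression(n=10, cluster_size_range=(3, 5),
                                                  p=5, s=2, seed=4)
        est = DebiasedLassoLMM(a=0.5, lam=0.1, random_state=0).fit(X, y, groups)
        assert np.allclose(est.predict(X), X @ est.coef_ + est.intercept_)
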