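"""REML estimation of random-intercept linear mixed models.

These are the low-dimensional workhorses of the framework: one fit per
mediator (mediator ~ exposure + covariates + patient intercept) and the
community-level outcome model.  The bootstrap re-runs them tens of
thousands of times, so the solver profiles the REML criterion down to a
single scalar parameter, the variance ratio theta = psi / sigma_e^2, and
evaluates it from per-cluster sufficient statistics in closed form.

Model, per cluster i with m_i observations:

    y_i = X_i beta + gamma_i 1 + eps_i,
    gamma_i ~ (0, psi),  eps_i ~ (0, sigma_e^2 I).

Given theta, GLS fixed effects and the profiled residual variance have
closed forms via the Sherman-Morrison identity
(I + theta J)^{-1} = I - theta/(1 + theta m) J.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

_LOG_THETA_LO = -10.0
_LOG_THETA_HI = 16.0
_DEGENERATE_LOG_THETA = 15.0


class ConvergenceError(RuntimeError):
    """REML optimization failed to converge; carries the iteration trace."""


def _cluster_stats(X, y, groups):
    """Per-cluster sufficient statistics for the profiled REML criterion.

    Requires cluster-contiguous rows; returns (m, G, g, d, h, yy) where for
    cluster i: m_i size, G_i = X_i'X_i, g_i = X_i'1, d_i = X_i'y_i,
    h_i = 1'y_i, yy = sum_i y_i'y_i.
    """
    _, starts, m = np.unique(groups, return_index=True, return_counts=True)
    order = np.argsort(starts)
    starts, m = starts[order], m[order]
    G = np.stack([X[s : s + k].T @ X[s : s + k] for s, k in zip(starts, m)])
    g = np.add.reduceat(X, starts, axis=0)
    d = np.add.reduceat(X * y[:, None], starts, axis=0)
    h = np.add.reduceat(y, starts)
    yy = float(y @ y)
    return m.astype(float), G, g, d, h, yy


def _profiled_criterion(thetas, stats, p, N):
    """-2 restricted log-likelihood (up to constants) at each theta.

    Vectorized over a 1-D array of theta values.  Returns (crit, beta, Q)
    with beta the GLS fixed effects and Q the weighted residual sum of
    squares at each theta.
    """
    m, G, g, d, h, yy = stats
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    c = thetas[:, None] / (1.0 + thetas[:, None] * m[None, :])  # (t, n)
    gg = np.einsum("ip,iq->ipq", g, g)
    A = G.sum(axis=0)[None] - np.einsum("ti,ipq->tpq", c, gg)
    b = d.sum(axis=0)[None] - np.einsum("ti,i,ip->tp", c, h, g)
    yVy = yy - c @ (h**2)
    sign, logdetA = np.linalg.slogdet(A)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    Q = yVy - np.einsum("tp,tp->t", beta, b)
    logdetV = np.log1p(thetas[:, None] * m[None, :]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = (N - p) * np.log(np.maximum(Q, 1e-300)) + logdetV + logdetA
    crit = np.where(sign <= 0, np.inf, crit)
    return crit, beta, Q


class RandomInterceptLMM(BaseEstimator, RegressorMixin):
    """Random-intercept linear mixed model fitted by REML.

    Parameters
    ----------
    fit_intercept : bool, default True
        Prepend an unpenalized intercept column to the design.
    grid_size : int, default 21
        Number of log-theta grid points bracketing the 1-D optimum before
        local refinement.
    tol : float, default 1e-10
        Absolute tolerance on log-theta in the local refinement.

    Attributes
    ----------
    coef_ : ndarray (p,)
        Fixed-effect estimates (excluding the intercept).
    intercept_ : float
    psi_ : float
        Random-intercept variance (>= 0; 0 at the boundary).
    sigma2_ : float
        Residual variance.
    theta_ : float
        Fitted variance ratio psi_/sigma2_ (inf in the degenerate
        zero-residual limit).
    converged_ : bool
    n_clusters_, n_obs_ : int
    """

    def __init__(self, fit_intercept=True, grid_size=21, tol=1e-10):
        self.fit_intercept = fit_intercept
        self.grid_size = grid_size
        self.tol = tol

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray(groups)
        if not (len(X) == len(y) == len(groups)):
            raise ValueError("X, y and groups must have equal length")
        X, y, groups = _contiguize(X, y, groups)
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(y)), X])
        N, p = X.shape
        n_clusters = len(np.unique(groups))
        if n_clusters < 2:
            raise ValueError("need at least 2 clusters for a random intercept")
        if N < p + 2:
            raise ValueError(f"N={N} too small for {p} fixed effects")
        if np.linalg.matrix_rank(X) < p:
            raise np.linalg.LinAlgError("singular fixed-effects design")

        stats = _cluster_stats(X, y, groups)
        m = stats[0]

        # exact-fit shortcut: OLS residual ~ 0 leaves no variance to split
        beta_ols, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta_ols) ** 2).sum())
        if rss <= 1e-12 * (float(y @ y) + 1.0):
            self._finalize(beta_ols, psi=0.0, sigma2=0.0, theta=0.0,
                           converged=True, n_clusters=n_clusters, N=N)
            return self

        grid = np.concatenate(
            [[0.0], np.exp(np.linspace(_LOG_THETA_LO, _LOG_THETA_HI, self.grid_size))]
        )
        crit, beta_g, Q_g = _profiled_criterion(grid, stats, p, N)
        k = int(np.argmin(crit))

        if k == 0:
            # boundary psi = 0: fixed effects are OLS on the raw design
            sigma2 = Q_g[0] / (N - p)
            self._finalize(beta_g[0], psi=0.0, sigma2=float(sigma2), theta=0.0,
                           converged=True, n_clusters=n_clusters, N=N)
            return self

        lo = np.log(grid[k - 1]) if k >= 2 else _LOG_THETA_LO - 2.0
        hi = np.log(grid[k + 1]) if k + 1 < len(grid) else _LOG_THETA_HI

        def f(t):
            return float(_profiled_criterion(np.exp(t), stats, p, N)[0][0])

        res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                              options={"xatol": self.tol})
        t_hat = float(res.x)
        if not res.success:
            raise ConvergenceError(f"REML 1-D optimization failed: {res}")

        # snap to the psi = 0 boundary when it is at least as good
        if crit[0] <= res.fun + 1e-9:
            sigma2 = Q_g[0] / (N - p)
            self._finalize(beta_g[0], psi=0.0, sigma2=float(sigma2), theta=0.0,
                           converged=True, n_clusters=n_clusters, N=N)
            return self

        if t_hat >= _DEGENERATE_LOG_THETA:
            # sigma_e^2 -> 0 limit: exact REML on cluster means
            self._fit_degenerate(stats, X, y, groups, p, N, n_clusters)
            return self

        crit_h, beta_h, Q_h = _profiled_criterion(np.exp(t_hat), stats, p, N)
        theta = float(np.exp(t_hat))
        sigma2 = float(Q_h[0] / (N - p))
        self._finalize(beta_h[0], psi=theta * sigma2, sigma2=sigma2, theta=theta,
                       converged=True, n_clusters=n_clusters, N=N)
        return self

    def _fit_degenerate(self, stats, X, y, groups, p, N, n_clusters):
        m, G, g, d, h, yy = stats
        Xbar = g / m[:, None]
        ybar = h / m
        beta, *_ = np.linalg.lstsq(Xbar, ybar, rcond=None)
        resid_means = ybar - Xbar @ beta
        psi = float((resid_means**2).sum() / max(n_clusters - p, 1))
        # residual variance from the within-cluster sum of squares
        rss_tot = yy - 2 * beta @ d.sum(axis=0) + beta @ G.sum(axis=0) @ beta
        between = float((m * resid_means**2).sum())
        wss = max(rss_tot - between, 0.0)
        sigma2 = wss / (N - n_clusters) if N > n_clusters else 0.0
        self._finalize(beta, psi=psi, sigma2=float(sigma2), theta=np.inf,
                       converged=True, n_clusters=n_clusters, N=N)

    def _finalize(self, beta, psi, sigma2, theta, converged, n_clusters, N):
        beta = np.asarray(beta, dtype=float).ravel()
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        self.psi_ = max(float(psi), 0.0)
        self.sigma2_ = float(sigma2)
        self.theta_ = theta
        self.converged_ = bool(converged)
        self.n_clusters_ = int(n_clusters)
        self.n_obs_ = int(N)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_ + self.intercept_


def _contiguize(X, y, groups):
    """Stable-sort rows so each cluster forms one contiguous block.

    Cluster blocks are ordered by first appearance and within-cluster row
    order is preserved, so estimates are invariant to relabeling and to
    sample order within clusters.
    """
    _, first = np.unique(groups, return_index=True)
    rank = {groups[i]: r for r, i in enumerate(np.sort(first))}
    key = np.array([rank[gv] for gv in groups])
    order = np.argsort(key, kind="stable")
    return X[order], y[order], groups[order]


# ---------------------------------------------------------------------------
# spec-surface wrappers
# ---------------------------------------------------------------------------

def fit_random_intercept_reml(y, fixed_design, cluster_ids, fit_intercept=False):
    """Fit a random-intercept model by REML on an explicit fixed design.

    ``fixed_design`` is used as given (no intercept added unless requested).
    """
    return RandomInterceptLMM(fit_intercept=fit_intercept).fit(
        fixed_design, y, cluster_ids
    )


def fit_mediator_model(mlog_t, T, C, cluster_ids):
    """Mediator model: mlog_t ~ T + C + intercept + patient intercept.

    Returns the fitted :class:`RandomInterceptLMM`; the exposure
    coefficient (delta_T for this mediator) is ``fit.coef_[0]``.
    """
    T = np.asarray(T, dtype=float).ravel()
    if len(np.unique(T)) < 2:
        raise ValueError("exposure has one level in this subset")
    cols = [T]
    if C is not None:
        C = np.asarray(C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[1]:
            cols.append(C)
    X = np.column_stack(cols)
    return RandomInterceptLMM(fit_intercept=True).fit(X, mlog_t, cluster_ids)
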