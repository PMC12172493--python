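"""Debiased lasso inference for fixed effects in high-dimensional linear
mixed models.

The estimation chain avoids estimating the random-effect variance psi and
the residual variance directly.  Instead each cluster's working covariance
is a proxy

    Sigma_a^i = a Z_i Z_i' + I   (random intercept: Z_i = 1, so a J + I)

with a single tuning scalar ``a`` chosen by cluster-level cross-validation.
Observations are whitened blockwise by Sigma_a^{-1/2}; the quasi-likelihood
lasso

    argmin_beta  1/(2 Tr(Sigma_a^{-1})) ||Ya - Xa beta||_2^2 + lambda ||beta||_1

uses the trace of the inverse proxy as the effective sample size.  Each
coordinate is then debiased with a correction score from a nodewise lasso,

    beta_j^db = beta_j + w_j'(Ya - Xa beta) / (w_j' Xa_j),
    w_j = Xa_j - Xa_{-j} kappa_j,

and its variance is the clusterwise sandwich sum
V_j = sum_i [ (w_j^i)' (Ya^i - Xa^i beta) ]^2 / (w_j' Xa_j)^2.

The lasso solves themselves are delegated to scikit-learn's coordinate
descent after rescaling the penalty: our objective equals sklearn's
1/(2N) ||r||^2 + alpha ||beta||_1 with alpha = lambda * Tr(Sigma_a^{-1}) / N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import lasso_path

logger = logging.getLogger("medimix")

DEFAULT_A_CANDIDATES = (0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
#: multiplier grid {2.0, 1.9, ..., 0.1} on the base rate sqrt(2 log p / N)
DEFAULT_MULTIPLIERS = tuple(np.round(np.arange(20, 0, -1) * 0.1, 10))


# ---------------------------------------------------------------------------
# covariance proxy and whitening
# ---------------------------------------------------------------------------

@dataclass
class CovarianceProxy:
    """Blockwise working covariance a*J + I for random-intercept clusters.

    For a cluster of size m the eigenvalues are (1 + a m) on the constant
    vector and 1 on its orthocomplement, giving closed forms for the
    inverse square root and for Tr(Sigma_a^{-1}) = (m - 1) + 1/(1 + a m).
    """

    a: float
    cluster_sizes: np.ndarray
    starts: np.ndarray = field(init=False)
    trace_inv: float = field(init=False)

    def __post_init__(self):
        if not np.isfinite(self.a) or self.a < 0:
            raise ValueError(f"proxy tuning parameter a must be finite >= 0, got {self.a}")
        self.cluster_sizes = np.asarray(self.cluster_sizes, dtype=int)
        if (self.cluster_sizes < 1).any():
            raise ValueError("every cluster must have at least one observation")
        self.starts = np.concatenate([[0], np.cumsum(self.cluster_sizes)[:-1]])
        m = self.cluster_sizes.astype(float)
        self.trace_inv = float(((m - 1.0) + 1.0 / (1.0 + self.a * m)).sum())

    @property
    def n_obs(self) -> int:
        return int(self.cluster_sizes.sum())

    def block(self, i: int) -> np.ndarray:
        m = int(self.cluster_sizes[i])
        return self.a * np.ones((m, m)) + np.eye(m)

    def inv_sqrt_block(self, i: int) -> np.ndarray:
        m = int(self.cluster_sizes[i])
        s = (1.0 + self.a * m) ** -0.5
        return np.eye(m) + ((s - 1.0) / m) * np.ones((m, m))

    def inv_block(self, i: int) -> np.ndarray:
        m = int(self.cluster_sizes[i])
        c = self.a / (1.0 + self.a * m)
        return np.eye(m) - c * np.ones((m, m))


def build_covariance_proxy(cluster_sizes, a: float) -> CovarianceProxy:
    """Construct the working covariance proxy from cluster sizes and ``a``."""
    return CovarianceProxy(a=float(a), cluster_sizes=np.asarray(cluster_sizes))


@dataclass
class WhitenedData:
    """Whitened observations plus the raw data and block structure."""

    Xa: np.ndarray
    ya: np.ndarray
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    proxy: CovarianceProxy

    @property
    def trace_inv(self) -> float:
        return self.proxy.trace_inv


def _block_whiten(M, proxy: CovarianceProxy):
    """Left-multiply each cluster block of M by Sigma_a^{-1/2} (closed form)."""
    M = np.asarray(M, dtype=float)
    vec = M.ndim == 1
    if vec:
        M = M[:, None]
    m = proxy.cluster_sizes.astype(float)
    s = (1.0 + proxy.a * m) ** -0.5
    sums = np.add.reduceat(M, proxy.starts, axis=0)
    scale = np.repeat((s - 1.0) / m, proxy.cluster_sizes)
    out = M + scale[:, None] * np.repeat(sums, proxy.cluster_sizes, axis=0)
    return out[:, 0] if vec else out


def whiten(X, y, proxy: CovarianceProxy, groups=None) -> WhitenedData:
    """Whiten (X, y) blockwise; rows must be cluster-contiguous."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != proxy.n_obs or len(y) != proxy.n_obs:
        raise ValueError(
            f"row count {len(y)} does not match proxy block total {proxy.n_obs}"
        )
    if groups is None:
        groups = np.repeat(np.arange(len(proxy.cluster_sizes)), proxy.cluster_sizes)
    return WhitenedData(
        Xa=_block_whiten(X, proxy),
        ya=_block_whiten(y, proxy),
        X=X,
        y=y,
        groups=np.asarray(groups),
        proxy=proxy,
    )


def cluster_sizes_from_groups(groups):
    """Cluster sizes in first-appearance order; requires contiguous blocks."""
    groups = np.asarray(groups)
    change = np.concatenate([[True], groups[1:] != groups[:-1]])
    starts = np.flatnonzero(change)
    labels = groups[starts]
    if len(np.unique(labels)) != len(labels):
        raise ValueError("groups are not cluster-contiguous")
    return np.diff(np.concatenate([starts, [len(groups)]]))


# ---------------------------------------------------------------------------
# lasso on whitened data (Eq. 5 scaling)
# ---------------------------------------------------------------------------

@dataclass
class LassoFit:
    beta: np.ndarray
    lam: float
    objective: float
    support: np.ndarray


def lambda_grid(p: int, N: int, multipliers=DEFAULT_MULTIPLIERS) -> np.ndarray:
    """Penalty grid {multipliers} * sqrt(2 log(p) / N), descending."""
    if p < 2:
        logger.warning("lambda_grid: p < 2, using fixed fallback base rate")
        base = np.sqrt(2.0 / N)
    else:
        base = np.sqrt(2.0 * np.log(p) / N)
    return np.asarray(sorted(multipliers, reverse=True)) * base


def _project_out(U, M):
    """Residualize columns of M against span(U) (exact unpenalized profiling)."""
    Q, _ = np.linalg.qr(U)
    return M - Q @ (Q.T @ M)


def lasso_fixed_effects(data: WhitenedData, lam: float, unpenalized=()):
    """Solve the effective-sample-size-scaled lasso on whitened data.

    ``unpenalized`` columns (e.g. the intercept) are profiled out exactly:
    the quadratic is minimized over them in closed form, the lasso runs on
    the residualized remainder, and their coefficients are recovered by
    least squares.  ``lam = 0`` falls back to least squares.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Xa, ya = data.Xa, data.ya
    N, p = Xa.shape
    tr = data.trace_inv
    unpen = np.asarray(sorted(unpenalized), dtype=int)
    pen = np.setdiff1d(np.arange(p), unpen)

    alpha = lam * tr / N
    if alpha < 1e-12:
        beta, *_ = np.linalg.lstsq(Xa, ya, rcond=None)
    else:
        if len(unpen):
            U = Xa[:, unpen]
            Xp = _project_out(U, Xa[:, pen])
            yp = _project_out(U, ya[:, None])[:, 0]
        else:
            Xp, yp = Xa[:, pen], ya
        beta = np.zeros(p)
        if len(pen):
            _, coefs, dual_gaps = lasso_path(
                Xp, yp, alphas=[alpha], max_iter=100_000, tol=1e-10
            )
            if dual_gaps[0] > 1e-3 * max(np.dot(yp, yp), 1e-10):
                raise RuntimeError(
                    f"lasso did not converge: duality gap {dual_gaps[0]:.3e}"
                )
            beta[pen] = coefs[:, 0]
        if len(unpen):
            U = Xa[:, unpen]
            resid = ya - Xa[:, pen] @ beta[pen]
            beta[unpen], *_ = np.linalg.lstsq(U, resid, rcond=None)

    resid = ya - Xa @ beta
    obj = float(resid @ resid) / (2.0 * tr) + lam * float(np.abs(beta[pen]).sum())
    return LassoFit(
        beta=beta, lam=float(lam), objective=obj,
        support=np.flatnonzero(np.abs(beta) > 1e-12),
    )


def eq_objective(beta, data: WhitenedData, lam: float, unpenalized=()):
    """Quasi-likelihood lasso objective at ``beta`` (penalized coords only)."""
    resid = data.ya - data.Xa @ beta
    pen = np.setdiff1d(np.arange(data.Xa.shape[1]), np.asarray(list(unpenalized), dtype=int))
    return float(resid @ resid) / (2.0 * data.trace_inv) + lam * float(
        np.abs(np.asarray(beta)[pen]).sum()
    )


# ---------------------------------------------------------------------------
# cross-validation over clusters
# ---------------------------------------------------------------------------

def cluster_kfold(groups, n_folds: int, rng) -> list:
    """K-fold split at cluster level; returns (train_rows, test_rows) pairs.

    Whole clusters are assigned to folds with a seeded shuffle, so no
    cluster is ever split across train and test.
    """
    groups = np.asarray(groups)
    labels = groups[np.sort(np.unique(groups, return_index=True)[1])]
    if len(labels) < n_folds:
        raise ValueError(f"{len(labels)} clusters < {n_folds} folds")
    perm = rng.permutation(len(labels))
    folds = np.array_split(perm, n_folds)
    out = []
    for fold in folds:
        test_labels = set(labels[fold])
        test_mask = np.isin(groups, list(test_labels))
        out.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
    return out


def _cv_sse_over_lambda(X, y, groups, a, lam_values, folds, unpenalized=()):
    """Summed held-out raw-scale SSE per lambda for one proxy setting ``a``.

    Training data are whitened with the training clusters' proxy blocks;
    held-out error is measured on the raw scale, ||Y_held - X_held beta||^2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    unpen = np.asarray(sorted(unpenalized), dtype=int)
    pen = np.setdiff1d(np.arange(p), unpen)
    sse = np.zeros(len(lam_values))
    for train, test in folds:
        sizes = cluster_sizes_from_groups(groups[train])
        proxy = build_covariance_proxy(sizes, a)
        Xa = _block_whiten(X[train], proxy)
        ya = _block_whiten(y[train], proxy)
        alphas = np.asarray(lam_values) * proxy.trace_inv / len(train)
        if len(unpen):
            U = Xa[:, unpen]
            Q, _ = np.linalg.qr(U)
            Xp = Xa[:, pen] - Q @ (Q.T @ Xa[:, pen])
            yp = ya - Q @ (Q.T @ ya)
        else:
            Xp, yp = Xa[:, pen], ya
        _, coefs, _ = lasso_path(Xp, yp, alphas=alphas, max_iter=50_000, tol=1e-8)
        # recover unpenalized coordinates per lambda, then raw-scale error
        for k in range(len(lam_values)):
            beta = np.zeros(p)
            beta[pen] = coefs[:, k]
            if len(unpen):
                resid = ya - Xa[:, pen] @ beta[pen]
                beta[unpen], *_ = np.linalg.lstsq(Xa[:, unpen], resid, rcond=None)
            err = y[test] - X[test] @ beta
            sse[k] += float(err @ err)
    return sse


def select_a(
    X, y, groups, candidate_as=DEFAULT_A_CANDIDATES,
    multipliers=DEFAULT_MULTIPLIERS, n_folds=5, rng=None, unpenalized=(),
):
    """Choose the proxy tuning parameter ``a`` by cluster-level K-fold CV.

    For each candidate the lasso path over the full multiplier grid is
    cross-validated and the candidate with the smallest (min over lambda)
    held-out ||Y - X beta||^2 wins; ties go to the smallest ``a``.
    """
    candidate_as = sorted(float(a) for a in candidate_as)
    if not candidate_as:
        raise ValueError("candidate_as must be non-empty")
    if any(a < 0 for a in candidate_as):
        raise ValueError("candidate a values must be >= 0")
    if len(candidate_as) == 1:
        return candidate_as[0]
    rng = np.random.default_rng(rng)
    folds = cluster_kfold(groups, n_folds, rng)
    N, p = np.asarray(X).shape
    lams = lambda_grid(p, N, multipliers)
    scores = [
        _cv_sse_over_lambda(X, y, groups, a, lams, folds, unpenalized).min()
        for a in candidate_as
    ]
    return candidate_as[int(np.argmin(scores))]


def select_lambda(
    data: WhitenedData, multipliers=DEFAULT_MULTIPLIERS, n_folds=5, rng=None,
    unpenalized=(),
):
    """Choose lambda on the default grid by cluster-level K-fold CV.

    Ties break toward the larger (sparser) lambda.
    """
    if len(multipliers) == 0:
        raise ValueError("multiplier grid must be non-empty")
    N, p = data.Xa.shape
    lams = lambda_grid(p, N, multipliers)
    if len(lams) == 1:
        return float(lams[0])
    rng = np.random.default_rng(rng)
    folds = cluster_kfold(data.groups, n_folds, rng)
    sse = _cv_sse_over_lambda(
        data.X, data.y, data.groups, data.proxy.a, lams, folds, unpenalized
    )
    return float(lams[int(np.argmin(sse))])  # first minimum = largest lambda


# ---------------------------------------------------------------------------
# nodewise correction scores and debiasing
# ---------------------------------------------------------------------------

@dataclass
class NodewiseScore:
    j: int
    w: np.ndarray
    kappa: np.ndarray
    lam: float


def nodewise_score(
    data: WhitenedData, j: int, lambda_j=None,
    multipliers=DEFAULT_MULTIPLIERS, n_folds=5, rng=None,
) -> NodewiseScore:
    """Correction score for coordinate j via a nodewise lasso.

    Regresses the whitened column Xa_j on all remaining whitened columns
    with the same effective-sample-size scaling; lambda_j is selected by
    cluster-level CV over the multiplier grid unless given.  The residual
    w_j = Xa_j - Xa_{-j} kappa_j must retain overlap with Xa_j.
    """
    Xa = data.Xa
    N, p = Xa.shape
    if not 0 <= j < p:
        raise ValueError(f"coordinate {j} out of range for p={p}")
    xj = Xa[:, j]
    others = np.delete(np.arange(p), j)
    if len(others) == 0:
        return NodewiseScore(j=j, w=xj.copy(), kappa=np.zeros(0), lam=0.0)
    Xo = Xa[:, others]
    tr = data.trace_inv
    if lambda_j is None:
        lams = lambda_grid(p, N, multipliers)
        rng = np.random.default_rng(rng)
        folds = cluster_kfold(data.groups, n_folds, rng)
        sse = np.zeros(len(lams))
        for train, test in folds:
            sizes = cluster_sizes_from_groups(data.groups[train])
            tr_train = build_covariance_proxy(sizes, data.proxy.a).trace_inv
            alphas = lams * tr_train / len(train)
            _, coefs, _ = lasso_path(
                Xo[train], xj[train], alphas=alphas, max_iter=50_000, tol=1e-8
            )
            resid = xj[test, None] - Xo[test] @ coefs
            sse += (resid**2).sum(axis=0)
        lambda_j = float(lams[int(np.argmin(sse))])
    alpha = lambda_j * tr / N
    if alpha < 1e-12:
        kappa, *_ = np.linalg.lstsq(Xo, xj, rcond=None)
    else:
        _, coefs, _ = lasso_path(Xo, xj, alphas=[alpha], max_iter=100_000, tol=1e-10)
        kappa = coefs[:, 0]
    w = xj - Xo @ kappa
    if abs(w @ xj) <= 1e-10 * max(xj @ xj, 1e-30):
        raise ValueError(f"degenerate correction score for coordinate {j}")
    return NodewiseScore(j=j, w=w, kappa=kappa, lam=float(lambda_j))


@dataclass
class DebiasedFit:
    """Per-coordinate debiased estimates with clusterwise variance."""

    coords: np.ndarray
    beta_lasso: np.ndarray       # full lasso vector (length p)
    beta_db: np.ndarray          # debiased estimates, one per coord
    variance: np.ndarray
    se: np.ndarray
    nodewise_lambda: np.ndarray
    a: float
    lam: float


def debias(fit: LassoFit, scores, data: WhitenedData) -> DebiasedFit:
    """Apply the one-step correction and the clusterwise variance estimate."""
    Xa, ya = data.Xa, data.ya
    resid = ya - Xa @ fit.beta
    starts = data.proxy.starts
    coords, beta_db, var, nlam = [], [], [], []
    for sc in scores:
        j = sc.j
        den = float(sc.w @ Xa[:, j])
        if den == 0.0:
            raise ValueError(f"degenerate correction score for coordinate {j}")
        beta_db.append(fit.beta[j] + float(sc.w @ resid) / den)
        cluster_terms = np.add.reduceat(sc.w * resid, starts)
        var.append(float((cluster_terms**2).sum()) / den**2)
        coords.append(j)
        nlam.append(sc.lam)
    var = np.asarray(var)
    return DebiasedFit(
        coords=np.asarray(coords),
        beta_lasso=fit.beta,
        beta_db=np.asarray(beta_db),
        variance=var,
        se=np.sqrt(var),
        nodewise_lambda=np.asarray(nlam),
        a=data.proxy.a,
        lam=fit.lam,
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class DebiasedLassoLMM(BaseEstimator, RegressorMixin):
    """Debiased lasso for fixed effects of a random-intercept LMM.

    Runs the full chain: select ``a`` by cluster CV, whiten, select lambda
    on the {2.0,...,0.1} * sqrt(2 log p / N) grid, solve the scaled lasso,
    compute nodewise correction scores, and debias the requested
    coordinates.  An unpenalized intercept is included by default and is
    excluded from debiasing.

    Parameters
    ----------
    a : float or "cv"
    a_candidates : sequence of float
    lam : float or "cv"
    multipliers : sequence of float
        Lambda grid multipliers on the base rate sqrt(2 log p / N).
    cv : int, default 5
        Cluster-level folds.
    debias_coords : "all" or sequence of int
        Column indices of X (before the intercept is prepended) to debias.
    fit_intercept : bool, default True
    standardize : bool, default False
        Scale columns to unit standard deviation before fitting
        (coefficients are reported on the original scale).
    random_state : int, default 0
        Seeds the CV fold assignment.

    Attributes
    ----------
    a_, lambda_ : selected tuning parameters
    trace_inv_ : effective sample size Tr(Sigma_a^{-1})
    coef_ : lasso coefficients (original column order, intercept excluded)
    intercept_ : unpenalized intercept
    coef_db_, se_ : debiased estimates and standard errors, NaN where a
        coordinate was not debiased
    """

    def __init__(
        self, a="cv", a_candidates=DEFAULT_A_CANDIDATES, lam="cv",
        multipliers=DEFAULT_MULTIPLIERS, cv=5, debias_coords="all",
        fit_intercept=True, standardize=False, random_state=0,
    ):
        self.a = a
        self.a_candidates = a_candidates
        self.lam = lam
        self.multipliers = multipliers
        self.cv = cv
        self.debias_coords = debias_coords
        self.fit_intercept = fit_intercept
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y, groups):
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = None
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray(groups)
        X, y, groups = _sort_clusters(X, y, groups)

        scale = np.ones(X.shape[1])
        if self.standardize:
            scale = X.std(axis=0, ddof=0)
            scale[scale == 0] = 1.0
            X = X / scale

        if self.fit_intercept:
            Xd = np.column_stack([np.ones(len(y)), X])
            unpen = (0,)
            offset = 1
        else:
            Xd = X
            unpen = ()
            offset = 0

        rng_folds = np.random.default_rng(self.random_state)
        fold_seed = int(rng_folds.integers(2**31 - 1))

        a = self.a
        if a == "cv":
            a = select_a(
                Xd, y, groups, self.a_candidates, self.multipliers, self.cv,
                rng=fold_seed, unpenalized=unpen,
            )
        proxy = build_covariance_proxy(cluster_sizes_from_groups(groups), float(a))
        data = whiten(Xd, y, proxy, groups)

        lam = self.lam
        if lam == "cv":
            lam = select_lambda(
                data, self.multipliers, self.cv, rng=fold_seed, unpenalized=unpen
            )
        lasso = lasso_fixed_effects(data, float(lam), unpenalized=unpen)

        if self.debias_coords == "all":
            coords = list(range(X.shape[1]))
        else:
            coords = list(self.debias_coords)
        scores = [
            nodewise_score(
                data, j + offset, multipliers=self.multipliers,
                n_folds=self.cv, rng=fold_seed,
            )
            for j in coords
        ]
        dbf = debias(lasso, scores, data)

        self.a_ = float(a)
        self.lambda_ = float(lam)
        self.trace_inv_ = proxy.trace_inv
        logger.info(
            "DebiasedLassoLMM: selected a=%g lambda=%g (fold seed %d, "
            "Tr(Sigma_a^-1)=%.2f)", self.a_, self.lambda_, fold_seed,
            self.trace_inv_,
        )
        self.intercept_ = float(lasso.beta[0] / 1.0) if self.fit_intercept else 0.0
        self.coef_ = lasso.beta[offset:] / scale
        self.coef_db_ = np.full(X.shape[1], np.nan)
        self.se_ = np.full(X.shape[1], np.nan)
        for k, j in enumerate(coords):
            self.coef_db_[j] = dbf.beta_db[k] / scale[j]
            self.se_[j] = dbf.se[k] / scale[j]
        self.nodewise_lambda_ = dbf.nodewise_lambda
        self.support_ = np.flatnonzero(np.abs(self.coef_) > 1e-12)
        self.debias_fit_ = dbf
        return self

    def predict(self, X):
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def _sort_clusters(X, y, groups):
    """Group rows into contiguous cluster blocks (first-appearance order)."""
    _, first = np.unique(groups, return_index=True)
    rank = {groups[i]: r for r, i in enumerate(np.sort(first))}
    key = np.array([rank[gv] for gv in groups])
    order = np.argsort(key, kind="stable")
    return X[order], y[order], groups[order]
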