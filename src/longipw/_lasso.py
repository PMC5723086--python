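"""Weighted L1-penalized logistic regression paths.

Solves, over a decreasing penalty grid ``lambda``,

    min_{b0, b}  (1/n) sum_i w_i [log(1 + exp(eta_i)) - y_i eta_i]
                 + lambda * sum_j |b_j|,        eta = b0 + X b,

with observation weights ``w`` scaled to mean one (so a unit weight is one
subject) and an unpenalized intercept.  The algorithm is the standard
iteratively-reweighted-least-squares outer loop with cyclic coordinate
descent on the penalized working least-squares problem, warm-started along
the path.  Predictors are (by default) centred and scaled by their weighted
standard deviation before penalization and the coefficients mapped back,
matching common practice for indicator designs.

This module is deliberately self-contained: the screening and propensity
stages need hundreds of cross-validated paths per analysis, and the
warm-started path is what makes that affordable.  Correctness is checked in
the test-suite against independent solvers at matched penalties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

try:  # pragma: no cover - thin JIT shim
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap

__all__ = [
    "LassoPath",
    "CVLassoResult",
    "lasso_logistic_path",
    "cv_lasso_logistic",
    "fit_weighted_logistic",
    "weighted_deviance",
]

_PMIN = 1e-5  # probability floor in the IRLS working weights


def _normalize_weights(w: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights have shape {w.shape}, expected ({n},)")
    if np.any(w <= 0):
        raise ValueError("observation weights must be strictly positive")
    return w * (n / w.sum())


@dataclass
class LassoPath:
    """A fitted penalty path.

    ``coefs`` is (n_lambda, p) on the original (unstandardized) predictor
    scale; ``intercepts`` is (n_lambda,).  ``lambdas`` decreases.
    """

    lambdas: np.ndarray
    coefs: np.ndarray
    intercepts: np.ndarray
    n_iter: np.ndarray = field(repr=False, default=None)

    def entry_lambda(self, j: int, tol: float = 0.0) -> float:
        """Largest penalty at which predictor ``j`` is active (0 if never)."""
        active = np.abs(self.coefs[:, j]) > tol
        if not active.any():
            return 0.0
        return float(self.lambdas[np.argmax(active)])


@dataclass
class CVLassoResult:
    path: LassoPath
    lambda_opt: float
    cv_deviance: np.ndarray  # mean held-out deviance per lambda
    lambda_opt_index: int


def _lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    n_lambda: int,
    lambda_min_ratio: float,
) -> np.ndarray:
    n = len(y)
    pbar = np.average(y, weights=w)
    grad = (w * (y - pbar)) @ X / n
    lam_max = np.max(np.abs(grad))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


@_njit(cache=False)
def _cd_sweeps(G, u, bA, b0, q, s_zr, zsum, n, lam, tol):
    """Cyclic coordinate descent on one penalized WLS subproblem.

    Operates purely on active-set-dimension quantities (Gram block ``G``,
    weighted column means ``u``); mutates ``bA`` in place and returns the
    updated intercept and the largest coefficient change seen.
    """
    a = bA.shape[0]
    total = 0.0
    for _ in range(20):
        delta = 0.0
        ub = 0.0
        for k in range(a):
            ub += u[k] * bA[k]
        b0_new = (s_zr - n * ub) / zsum
        d = abs(b0_new - b0)
        if d > delta:
            delta = d
        b0 = b0_new
        for k in range(a):
            vk = G[k, k]
            if vk <= 0:
                continue
            gb = 0.0
            for j in range(a):
                gb += G[k, j] * bA[j]
            grad = q[k] - b0 * u[k] - gb + vk * bA[k]
            mag = abs(grad) - lam
            bnew = 0.0
            if mag > 0.0:
                bnew = mag / vk if grad > 0 else -mag / vk
            if bnew != bA[k]:
                d = abs(bnew - bA[k])
                if d > delta:
                    delta = d
                bA[k] = bnew
        if delta > total:
            total = delta
        if delta < 0.1 * tol:
            break
    return b0, total


class _PathEngine:
    """IRLS + covariance-update coordinate descent with warm starts.

    The quadratic subproblems run entirely in active-set dimension on a
    cached weighted Gram matrix; the IRLS curvature is refreshed (and the
    Gram rebuilt) only when the fitted probabilities have drifted enough to
    matter, which along a warm-started path is rare.  KKT checks always use
    the exact logistic gradient, so the zero pattern is that of the true
    penalized optimum.
    """

    def __init__(self, Xs: np.ndarray, y: np.ndarray, w: np.ndarray,
                 tol: float, max_mm: int):
        self.Xs, self.y, self.w = Xs, y, w
        self.n, self.p = Xs.shape
        self.tol, self.max_mm = tol, max_mm
        self.active: list[int] = []
        pbar = min(max(np.average(y, weights=w), _PMIN), 1 - _PMIN)
        self.b0 = float(np.log(pbar / (1 - pbar)))
        self.bA = np.empty(0)
        self.eta = np.full(self.n, self.b0)
        self._rebuild(np.full(self.n, pbar))

    def _rebuild(self, prob: np.ndarray) -> None:
        """Recompute curvature weights and the active-set Gram blocks."""
        pq = np.clip(prob * (1 - prob), _PMIN, None)
        self.c = pq  # curvature per observation (unit-weight scale)
        self.z = self.w * pq
        self.zsum = self.z.sum()
        self.pq_built = pq
        XA = self.Xs[:, self.active]
        ZA = XA * self.z[:, None]
        self.G = (ZA.T @ XA) / self.n
        self.u = ZA.sum(axis=0) / self.n

    def _activate(self, cols: np.ndarray) -> None:
        for c in cols:
            zx = self.z * self.Xs[:, c]
            cross = (zx @ self.Xs[:, self.active]) / self.n if self.active \
                else np.empty(0)
            a = len(self.active)
            G = np.empty((a + 1, a + 1))
            G[:a, :a] = self.G
            G[a, :a] = cross
            G[:a, a] = cross
            G[a, a] = (zx @ self.Xs[:, c]) / self.n
            self.G = G
            self.u = np.append(self.u, zx.sum() / self.n)
            self.active.append(int(c))
            self.bA = np.append(self.bA, 0.0)

    def _subproblem(self, r: np.ndarray, lam: float) -> float:
        """CD sweeps on the current quadratic; returns max change."""
        z, n = self.z, self.n
        s_zr = z @ r
        a = len(self.active)
        q = ((z * r) @ self.Xs[:, self.active]) / n if a else np.empty(0)
        self.b0, total = _cd_sweeps(
            self.G, self.u, self.bA, self.b0, q, s_zr, self.zsum,
            float(n), lam, self.tol)
        return total

    def solve(self, lam: float) -> int:
        """Advance the warm state to the optimum at penalty ``lam``."""
        n_it = 0
        while True:
            for _ in range(self.max_mm):
                n_it += 1
                prob = expit(self.eta)
                pq = prob * (1 - prob)
                if np.max(np.abs(pq - self.pq_built)
                          / np.maximum(self.pq_built, 0.02)) > 0.5:
                    self._rebuild(prob)
                r = self.eta + (self.y - prob) / self.c
                change = self._subproblem(r, lam)
                self.eta = self.b0 + (
                    self.Xs[:, self.active] @ self.bA if self.active else 0.0)
                if change < self.tol:
                    break
            prob = expit(self.eta)
            grad = np.abs((self.w * (self.y - prob)) @ self.Xs) / self.n
            mask = np.ones(self.p, dtype=bool)
            mask[self.active] = False
            viol = np.flatnonzero(mask & (grad > lam * (1 + 1e-9)))
            if viol.size == 0:
                return n_it
            self._activate(viol)

    def coef(self) -> tuple[np.ndarray, float]:
        beta = np.zeros(self.p)
        if self.active:
            beta[self.active] = self.bA
        return beta, self.b0


def lasso_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    standardize: bool = True,
    tol: float = 1e-5,
    max_mm: int = 500,
) -> LassoPath:
    """Fit the full weighted logistic LASSO path.

    Parameters
    ----------
    X : (n, p) design, typically 0/1 indicator columns.
    y : (n,) binary response.
    weights : positive observation weights; rescaled internally to mean 1.
    lambdas : optional explicit grid (decreasing); otherwise ``n_lambda``
        log-spaced values from the smallest all-zero penalty down to
        ``lambda_min_ratio`` times it.
    standardize : scale predictors by their weighted sd before penalizing.
    tol : convergence tolerance on coefficient changes (standardized scale).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else _normalize_weights(weights, n)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")

    mu = (w @ X) / n
    if standardize:
        sd = np.sqrt((w @ (X - mu) ** 2) / n)
        sd[sd == 0] = 1.0
    else:
        sd = np.ones(p)
        mu = np.zeros(p)
    Xs = (X - mu) / sd

    if lambdas is None:
        lambdas = _lambda_grid(Xs, y, w, n_lambda, lambda_min_ratio)
    else:
        lambdas = np.asarray(lambdas, dtype=float)

    L = len(lambdas)
    coefs = np.zeros((L, p))
    intercepts = np.zeros(L)
    n_iter = np.zeros(L, dtype=int)

    engine = _PathEngine(Xs, y, w, tol=tol, max_mm=max_mm)
    for li, lam in enumerate(lambdas):
        n_iter[li] = engine.solve(lam)
        beta, b0 = engine.coef()
        coefs[li] = beta / sd
        intercepts[li] = b0 - (beta / sd) @ mu

    return LassoPath(lambdas=lambdas, coefs=coefs, intercepts=intercepts, n_iter=n_iter)


def weighted_deviance(
    y: np.ndarray, prob: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Mean weighted binomial deviance, -2/W * sum w_i loglik_i."""
    y = np.asarray(y, dtype=float)
    prob = np.clip(np.asarray(prob, dtype=float), _PMIN, 1 - _PMIN)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    ll = y * np.log(prob) + (1 - y) * np.log1p(-prob)
    return float(-2.0 * (w @ ll) / w.sum())


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold labels, response-stratified, in {0, ..., n_folds-1}."""
    fold = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def cv_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    standardize: bool = True,
) -> CVLassoResult:
    """Cross-validated path: the optimum minimizes weighted held-out deviance.

    Folds are stratified by response and drawn from ``seed``; the penalty
    grid is fixed from the full data so every fold shares it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else _normalize_weights(weights, n)

    full_path = lasso_logistic_path(
        X, y, w, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
        standardize=standardize,
    )
    lambdas = full_path.lambdas

    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, n_folds, rng)
    L = len(lambdas)
    dev_num = np.zeros(L)
    w_tot = 0.0
    for k in range(n_folds):
        test = fold == k
        train = ~test
        if len(np.unique(y[train])) < 2 or not test.any():
            continue
        sub = lasso_logistic_path(
            X[train], y[train], w[train], lambdas=lambdas,
            standardize=standardize,
        )
        eta = sub.intercepts[:, None] + sub.coefs @ X[test].T  # (L, n_test)
        prob = np.clip(expit(eta), _PMIN, 1 - _PMIN)
        ll = y[test] * np.log(prob) + (1 - y[test]) * np.log1p(-prob)
        dev_num += -2.0 * ll @ w[test]
        w_tot += w[test].sum()
    cv_dev = dev_num / w_tot
    opt = int(np.argmin(cv_dev))
    return CVLassoResult(
        path=full_path,
        lambda_opt=float(lambdas[opt]),
        cv_deviance=cv_dev,
        lambda_opt_index=opt,
    )


def fit_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    ridge: float = 0.0,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> tuple[float, np.ndarray, bool]:
    """Unpenalized (optionally ridge-stabilized) weighted logistic fit.

    Newton-Raphson on the weighted log-likelihood; ``ridge`` adds
    ``ridge/2 * |b|^2`` (intercept excluded) to the objective, used as a
    fallback under quasi-separation.  Returns (intercept, coefs, converged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else _normalize_weights(weights, n)
    Xa = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pbar = min(max(np.average(y, weights=w), _PMIN), 1 - _PMIN)
    beta[0] = np.log(pbar / (1 - pbar))
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0
    converged = False
    for _ in range(max_iter):
        eta = Xa @ beta
        prob = np.clip(expit(eta), _PMIN, 1 - _PMIN)
        grad = Xa.T @ (w * (y - prob)) - pen * beta
        z = w * prob * (1 - prob)
        H = (Xa * z[:, None]).T @ Xa + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return float(beta[0]), beta[1:], converged
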