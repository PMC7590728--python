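"""Elastic-net regression by cyclic coordinate descent.

Minimizes, for mixing parameter alpha in [0, 1] and penalty lam >= 0,

    (1/2n) * sum_j (y_j - b0 - x_j' b)^2
        + lam * ( alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 )

with predictors standardized to zero mean / unit variance (population
convention, divisor n) and the response centered. Coefficients are
soft-threshold updates cycled until the largest coefficient change in a
sweep falls below tolerance; a path over a descending penalty grid is
warm-started, with active-set sweeps between full passes. Returned
coefficients are de-standardized to the raw predictor scale.

The penalty grid follows common practice: log-spaced from
lam_max = max_j |x_j'(y - ybar)| / (n * alpha) — the smallest penalty at
which all coefficients are exactly zero — down to lam_max * min_ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "CVResult",
    "elastic_net_fit",
    "make_lambda_grid",
    "cross_validate",
    "enet_path",
    "kkt_violation",
    "ConvergenceError",
]

_TOL_DEFAULT = 1e-7
_MAX_ITER_DEFAULT = 100_000


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge; carries the last iterate."""

    def __init__(self, message: str, coefficients: np.ndarray):
        super().__init__(message)
        self.coefficients = coefficients


@dataclass
class CVResult:
    """Cross-validation curve over a penalty grid.

    ``selected_lambda`` is the grid value minimizing mean CV MSE, ties
    broken toward the larger (more penalized) value.
    """

    lambda_grid: np.ndarray
    cv_mse: np.ndarray
    cv_se: np.ndarray
    selected_lambda: float
    fold_seed: int
    k: int

    @property
    def selected_index(self) -> int:
        return int(np.nonzero(self.lambda_grid == self.selected_lambda)[0][0])


@njit(cache=True)
def _soft(z, g):
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


@njit(cache=True)
def _cd_path(X, y, lams, alpha, tol, max_iter):
    """Warm-started coordinate-descent path on standardized data.

    Returns (B, iters) with B of shape (n_lambda, p). Columns of X are
    assumed centered with population variance in `xvar` computed here;
    zero-variance columns stay at zero.
    """
    n, p = X.shape
    nlam = lams.shape[0]
    B = np.zeros((nlam, p))
    iters = np.zeros(nlam, dtype=np.int64)
    beta = np.zeros(p)
    r = y.copy()
    xvar = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xvar[j] = s / n
    all_idx = np.arange(p)
    for k in range(nlam):
        lam = lams[k]
        l1 = lam * alpha
        denom_base = lam * (1.0 - alpha)
        it = 0
        while it < max_iter:
            # full pass to find/refresh the active set
            dmax = 0.0
            for t in range(p):
                j = all_idx[t]
                if xvar[j] == 0.0:
                    continue
                old = beta[j]
                rho = old * xvar[j]
                col = X[:, j]
                acc = 0.0
                for i in range(n):
                    acc += col[i] * r[i]
                rho += acc / n
                new = _soft(rho, l1) / (xvar[j] + denom_base)
                if new != old:
                    d = new - old
                    for i in range(n):
                        r[i] -= col[i] * d
                    beta[j] = new
                    ad = abs(d)
                    if ad > dmax:
                        dmax = ad
            it += 1
            if dmax < tol:
                break
            # cheap sweeps on the current active set
            active = np.nonzero(beta)[0]
            while it < max_iter:
                dmax = 0.0
                for t in range(active.shape[0]):
                    j = active[t]
                    old = beta[j]
                    rho = old * xvar[j]
                    col = X[:, j]
                    acc = 0.0
                    for i in range(n):
                        acc += col[i] * r[i]
                    rho += acc / n
                    new = _soft(rho, l1) / (xvar[j] + denom_base)
                    if new != old:
                        d = new - old
                        for i in range(n):
                            r[i] -= col[i] * d
                        beta[j] = new
                        ad = abs(d)
                        if ad > dmax:
                            dmax = ad
                it += 1
                if dmax < tol:
                    break
        B[k] = beta
        iters[k] = it
    return B, iters


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population (divisor n)
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    # column-major so coordinate descent walks contiguous columns
    return np.asfortranarray((X - mean) / sd_safe), mean, sd, sd_safe


def _check_finite(X: np.ndarray, y: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite entries")


def enet_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lams: np.ndarray,
    tol: float = _TOL_DEFAULT,
    max_iter: int = _MAX_ITER_DEFAULT,
):
    """Fit the whole descending-penalty path on raw-scale inputs.

    Returns ``(B_raw, intercepts)``: coefficients on the original predictor
    scale, one row per penalty, with matching intercepts.
    """
    X = np.asfortranarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_finite(X, y)
    Xs, mean, sd, sd_safe = _standardize(X)
    ybar = y.mean()
    yc = y - ybar
    lams = np.asarray(lams, dtype=np.float64)
    B_std, iters = _cd_path(Xs, yc, lams, float(alpha), float(tol), int(max_iter))
    if np.any(iters >= max_iter):
        k = int(np.nonzero(iters >= max_iter)[0][0])
        raise ConvergenceError(
            f"coordinate descent did not converge at lambda={lams[k]:g} "
            f"after {max_iter} sweeps",
            B_std[k] / sd_safe,
        )
    B_raw = B_std / sd_safe[None, :]
    intercepts = ybar - B_raw @ mean
    return B_raw, intercepts


def elastic_net_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    warm_start: np.ndarray | None = None,
    tol: float = _TOL_DEFAULT,
    max_iter: int = _MAX_ITER_DEFAULT,
) -> tuple[np.ndarray, float]:
    """Single elastic-net fit; returns raw-scale ``(coefficients, intercept)``.

    Predictors are standardized internally (and de-standardized on return),
    so passing already-standardized columns leaves coefficients unchanged.
    `warm_start` (raw scale) seeds the solver.
    """
    X = np.asfortranarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with n >= 2")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    _check_finite(X, y)
    lams = np.array([float(lam)])
    Xs, mean, sd, sd_safe = _standardize(X)
    ybar = y.mean()
    yc = y - ybar
    beta0 = np.zeros(X.shape[1]) if warm_start is None else np.asarray(warm_start) * sd_safe
    B, iters = _cd_path_from(Xs, yc, lams, float(alpha), float(tol), int(max_iter), beta0)
    if iters[0] >= max_iter:
        raise ConvergenceError(
            f"coordinate descent did not converge at lambda={lam:g}", B[0] / sd_safe
        )
    b_raw = B[0] / sd_safe
    intercept = float(ybar - b_raw @ mean)
    return b_raw, intercept


@njit(cache=True)
def _cd_path_from(X, y, lams, alpha, tol, max_iter, beta0):
    n, p = X.shape
    nlam = lams.shape[0]
    B = np.zeros((nlam, p))
    iters = np.zeros(nlam, dtype=np.int64)
    beta = beta0.copy()
    r = y - X @ beta
    xvar = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xvar[j] = s / n
    for k in range(nlam):
        lam = lams[k]
        l1 = lam * alpha
        denom_base = lam * (1.0 - alpha)
        it = 0
        while it < max_iter:
            dmax = 0.0
            for j in range(p):
                if xvar[j] == 0.0:
                    continue
                old = beta[j]
                rho = old * xvar[j]
                col = X[:, j]
                acc = 0.0
                for i in range(n):
                    acc += col[i] * r[i]
                rho += acc / n
                new = _soft(rho, l1) / (xvar[j] + denom_base)
                if new != old:
                    d = new - old
                    for i in range(n):
                        r[i] -= col[i] * d
                    beta[j] = new
                    ad = abs(d)
                    if ad > dmax:
                        dmax = ad
            it += 1
            if dmax < tol:
                break
        B[k] = beta
        iters[k] = it
    return B, iters


def make_lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_lambda: int = 100,
    min_ratio: float | None = None,
) -> np.ndarray:
    """Log-spaced descending penalty grid from lam_max down to lam_max*min_ratio.

    lam_max = max_j |x_j'(y - ybar)| / (n * alpha) on standardized
    predictors — by construction the first grid value yields the all-zero
    model. ``min_ratio=None`` follows the usual convention: 1e-4 when
    n > p, 1e-2 when p >= n (penalties below that floor only overfit in
    the overparameterized regime). alpha = 0 makes lam_max unbounded;
    supply an explicit grid then.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0 for automatic grid construction; "
                         "pass an explicit lambda grid for ridge (alpha = 0)")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if min_ratio is None:
        min_ratio = 1e-4 if X.shape[0] > X.shape[1] else 1e-2
    Xs, _, _, _ = _standardize(X)
    yc = y - y.mean()
    n = X.shape[0]
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * alpha)
    lam_max *= 1.0 + 1e-10  # guard float rounding so grid[0] is exactly null
    if lam_max <= 0:
        lam_max = 1e-3  # degenerate: y constant; any grid selects the null model
    if n_lambda == 1:
        return np.array([lam_max])
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _fold_assignments(n: int, k: int, seed: int) -> np.ndarray:
    """Simple random, unstratified near-equal folds; deterministic given seed."""
    rng = np.random.default_rng(seed)
    folds = np.tile(np.arange(k), n // k + 1)[:n]
    return rng.permutation(folds)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    grid: np.ndarray,
    k: int = 10,
    seed: int = 0,
    tol: float = _TOL_DEFAULT,
    max_iter: int = _MAX_ITER_DEFAULT,
) -> CVResult:
    """k-fold cross-validated MSE along a penalty path.

    Each fold's model is fit on the remaining folds (standardization
    recomputed per fold, path warm-started) and scored on the held-out
    fold; the selected penalty minimizes the mean CV MSE across folds,
    with ties broken toward the larger penalty.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    grid = np.asarray(grid, dtype=np.float64)
    assign = _fold_assignments(n, k, seed)
    fold_mse = np.empty((k, len(grid)))
    for fold in range(k):
        test = assign == fold
        train = ~test
        B_raw, intercepts = enet_path(
            X[train], y[train], alpha, grid, tol=tol, max_iter=max_iter
        )
        preds = X[test] @ B_raw.T + intercepts[None, :]
        err = preds - y[test, None]
        fold_mse[fold] = (err ** 2).mean(axis=0)
    cv_mse = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)
    # grid is descending, argmin returns the first (largest-penalty) minimum
    sel = int(np.argmin(cv_mse))
    return CVResult(
        lambda_grid=grid,
        cv_mse=cv_mse,
        cv_se=cv_se,
        selected_lambda=float(grid[sel]),
        fold_seed=seed,
        k=k,
    )


def kkt_violation(
    X: np.ndarray,
    y: np.ndarray,
    coef_raw: np.ndarray,
    alpha: float,
    lam: float,
) -> float:
    """Maximum KKT-condition violation of a raw-scale solution.

    On the standardized scale with residual r = yc - Xs b_std, optimality
    requires |(1/n) x_i'r - (1-alpha)*lam*b_i| = alpha*lam with matching
    sign for b_i != 0, and |(1/n) x_i'r| <= alpha*lam for b_i = 0. Serves
    as a solver-independent optimality oracle.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    Xs, mean, sd, sd_safe = _standardize(X)
    b_std = np.asarray(coef_raw, dtype=np.float64) * sd_safe
    yc = y - y.mean()
    n = X.shape[0]
    r = yc - Xs @ b_std
    g = Xs.T @ r / n
    viol = 0.0
    for j in range(X.shape[1]):
        if sd[j] == 0.0:
            continue
        if b_std[j] != 0.0:
            v = abs(g[j] - (1.0 - alpha) * lam * b_std[j] - alpha * lam * np.sign(b_std[j]))
        else:
            v = max(0.0, abs(g[j]) - alpha * lam)
        viol = max(viol, v)
    return float(viol)
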