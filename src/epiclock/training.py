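"""Training epigenetic clocks: a scikit-learn style estimator plus the
beta-matrix-level wrapper.

:class:`EpigeneticClock` regresses chronological age on CpG beta values by
elastic net (default mixing alpha = 0.5) with the penalty chosen by
10-fold cross-validation at minimum mean squared error — the standard
protocol for blood-based adult clocks. ``train_clock`` wraps it for
:class:`~epiclock.io.BetaMatrix` inputs and returns a sparse
:class:`~epiclock.io.ClockModel` holding only the selected CpGs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .enet import CVResult, cross_validate, enet_path, make_lambda_grid
from .io import DAYS_PER_YEAR, BetaMatrix, ClockModel

__all__ = ["EpigeneticClock", "train_clock"]


class EpigeneticClock(RegressorMixin, BaseEstimator):
    """Elastic-net chronological-age regressor with CV penalty selection.

    Parameters
    ----------
    alpha : float, default 0.5
        Elastic-net mixing parameter (1 = lasso, 0 = ridge). The blood-clock
        convention is 0.5.
    cv : int, default 10
        Number of cross-validation folds for penalty selection.
    n_lambda : int, default 100
        Length of the automatic log-spaced penalty grid.
    min_ratio : float or None, default None
        Smallest grid penalty as a fraction of lambda_max; None picks
        1e-4 when n > p and 1e-2 when p >= n.
    lambda_grid : array-like or None
        Explicit descending penalty grid; overrides automatic construction
        (required for alpha = 0).
    tol : float, default 1e-7
        Convergence tolerance on the maximum coefficient change per sweep.
    max_iter : int, default 100000
        Maximum coordinate-descent sweeps per penalty value.
    random_state : int, default 0
        Seed for the fold assignment.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Raw-scale coefficients (years per unit beta); mostly zero.
    intercept_ : float
        Raw-scale intercept (years).
    cv_result_ : CVResult
        The cross-validation curve and selected penalty.
    n_features_in_ : int
    """

    def __init__(
        self,
        alpha: float = 0.5,
        cv: int = 10,
        n_lambda: int = 100,
        min_ratio: float | None = None,
        lambda_grid=None,
        tol: float = 1e-7,
        max_iter: int = 100_000,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.cv = cv
        self.n_lambda = n_lambda
        self.min_ratio = min_ratio
        self.lambda_grid = lambda_grid
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        if np.ptp(y) == 0:
            raise ValueError("degenerate response: age is constant in the training set")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if np.any(np.diff(grid) > 0):
                raise ValueError("lambda_grid must be descending")
        else:
            grid = make_lambda_grid(X, y, self.alpha, self.n_lambda, self.min_ratio)
        cvres = cross_validate(
            X, y, self.alpha, grid,
            k=self.cv, seed=self.random_state,
            tol=self.tol, max_iter=self.max_iter,
        )
        # refit on the full training set along the path down to the
        # selected penalty (warm starts make this cheap and stable)
        sel = cvres.selected_index
        B, intercepts = enet_path(
            X, y, self.alpha, grid[: sel + 1], tol=self.tol, max_iter=self.max_iter
        )
        self.coef_ = B[sel]
        self.intercept_ = float(intercepts[sel])
        self.cv_result_ = cvres
        self.lambda_ = float(cvres.selected_lambda)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=np.float64)
        return X @ self.coef_ + self.intercept_

    @property
    def n_selected_(self) -> int:
        check_is_fitted(self, "coef_")
        return int(np.count_nonzero(self.coef_))


def _impute_probe_means(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Train-set probe-mean imputation; all-missing probes are dropped."""
    means = values.mean(axis=0, skipna=True)
    usable = means.notna()
    if not usable.all():
        values = values.loc[:, usable]
        means = means[usable]
    return values.fillna(means), means


def train_clock(
    train: BetaMatrix,
    alpha: float = 0.5,
    k: int = 10,
    n_lambda: int = 100,
    min_ratio: float | None = None,
    missing_policy: str = "impute_mean",
    seed: int = 0,
    age_unit: str = "years",
    probe_set_tag: str = "all",
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> tuple[ClockModel, CVResult]:
    """Fit a sparse clock on a beta matrix and return (ClockModel, CVResult).

    Missing betas are resolved by train-set probe-mean imputation (the
    means are stored in model provenance so prediction can reuse them);
    all-missing probes are dropped with a warning. With
    ``age_unit="days"`` the response is age in days (coefficients scale by
    365.25); the stored unit is recorded in provenance.
    """
    if train.n_samples < 20:
        raise ValueError(f"need >= 20 training samples, got {train.n_samples}")
    if missing_policy not in ("impute_mean", "error"):
        raise ValueError("missing_policy must be 'impute_mean' or 'error'")
    if age_unit not in ("years", "days"):
        raise ValueError("age_unit must be 'years' or 'days'")

    values = train.values
    if values.isna().any().any():
        if missing_policy == "error":
            raise ValueError("missing beta values present and policy is 'error'")
        import warnings

        n_all_missing = int(values.isna().all(axis=0).sum())
        if n_all_missing:
            warnings.warn(f"dropping {n_all_missing} all-missing probes")
        values, probe_means = _impute_probe_means(values)
    else:
        probe_means = values.mean(axis=0)

    y = train.ages.to_numpy(dtype=float)
    if age_unit == "days":
        y = y * DAYS_PER_YEAR

    est = EpigeneticClock(
        alpha=alpha, cv=k, n_lambda=n_lambda, min_ratio=min_ratio,
        tol=tol, max_iter=max_iter, random_state=seed,
    )
    est.fit(values.to_numpy(), y)

    nz = np.nonzero(est.coef_)[0]
    cpg_ids = values.columns.to_numpy()
    coefficients = {str(cpg_ids[j]): float(est.coef_[j]) for j in nz}
    model = ClockModel(
        intercept=est.intercept_,
        coefficients=coefficients,
        provenance={
            "alpha": alpha,
            "selected_lambda": est.lambda_,
            "n_train": train.n_samples,
            "probe_set": probe_set_tag,
            "seed": seed,
            "age_unit": age_unit,
            "n_lambda": n_lambda,
            "min_ratio": min_ratio,
            "k_folds": k,
            "probe_means": {str(cpg_ids[j]): float(probe_means.iloc[j]) for j in nz},
        },
    )
    return model, est.cv_result_
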