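"""Applying clocks and evaluating them: DNAm age, precision (Pearson r
with Fisher-Z bootstrap intervals), accuracy (median absolute prediction
error, the clock literature's "MAD"), epigenetic age acceleration (EAA)
under three calibrations, and two-group EAA comparison.

EAA is the residual of DNAm age regressed on chronological age: the
linear calibration uses ordinary least squares, so EAA has mean zero and
is uncorrelated with age by construction; the smoothing-spline and
piecewise-cubic calibrations absorb systematic non-linear bias (e.g.
underestimation in the oldest samples) so that EAA stays independent of
age even when the clock flattens at high ages. The regression direction
(DNAm age as response on chronological age) follows the EAA definition;
the reverse direction is available via ``direction="reverse"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .io import BetaMatrix, ClockModel

__all__ = [
    "PredictionResult",
    "EvaluationReport",
    "EAAResult",
    "GroupComparison",
    "predict_age",
    "accuracy_mad",
    "precision_r",
    "fisher_z",
    "fisher_z_inverse",
    "bootstrap_r_ci",
    "compute_eaa",
    "compare_groups_eaa",
    "evaluate_predictions",
]

#: Fisher-Z values are capped at arctanh(1 - 1e-12) so r = 1 resamples
#: stay finite.
Z_CAP = float(np.arctanh(1.0 - 1e-12))


@dataclass
class PredictionResult:
    """Per-sample DNAm age vs chronological age (years).

    ``residual`` is always ``dnam_age - chronological_age``.
    """

    frame: pd.DataFrame  # index sample_id; columns dnam_age, chronological_age, residual

    def __post_init__(self) -> None:
        f = self.frame
        expected = f["dnam_age"] - f["chronological_age"]
        if not np.allclose(f["residual"], expected, atol=1e-9, equal_nan=True):
            raise ValueError("residual must equal dnam_age - chronological_age")

    @classmethod
    def from_ages(cls, dnam_age, chronological_age, sample_ids=None) -> "PredictionResult":
        dnam = np.asarray(dnam_age, dtype=float)
        chron = np.asarray(chronological_age, dtype=float)
        idx = (
            pd.Index([str(s) for s in sample_ids], name="sample_id")
            if sample_ids is not None
            else pd.RangeIndex(len(dnam))
        )
        return cls(pd.DataFrame({
            "dnam_age": dnam,
            "chronological_age": chron,
            "residual": dnam - chron,
        }, index=idx))

    @property
    def dnam_age(self) -> pd.Series:
        return self.frame["dnam_age"]

    @property
    def chronological_age(self) -> pd.Series:
        return self.frame["chronological_age"]

    @property
    def residual(self) -> pd.Series:
        return self.frame["residual"]

    @property
    def n(self) -> int:
        return len(self.frame)


@dataclass
class EvaluationReport:
    r: float
    r_ci: tuple[float, float]
    mad: float
    n: int
    regression_slope: float
    regression_intercept: float


@dataclass
class EAAResult:
    """Calibrated epigenetic age acceleration (years) per sample.

    ``diagnostic_cor`` is the Pearson correlation of EAA with
    chronological age — identically zero (to float precision) for the
    linear calibration by OLS orthogonality. ``diagnostic_rank_cor`` is
    the Spearman rank correlation, which stays sensitive to *nonlinear*
    age dependence (e.g. old-age flattening) that the linear residuals
    cannot show in Pearson terms; it is the quantity the spline
    calibrations are meant to shrink.
    """

    eaa: pd.Series
    method: str
    knot: float | None
    diagnostic_cor: float
    diagnostic_rank_cor: float = 0.0
    fitted: pd.Series = field(repr=False, default=None)


@dataclass
class GroupComparison:
    reference: str
    comparison: str
    mean_difference: float
    ci: tuple[float, float]
    p_value: float
    test: str = "Welch two-sample t-test"


def predict_age(
    model: ClockModel,
    bm: BetaMatrix,
    missing_policy: str = "error",
) -> PredictionResult:
    """Apply the linear clock rule: intercept + sum of beta * coefficient.

    The prediction uses only the model's CpGs — extra probes and their
    order in `bm` are irrelevant. Missing model CpGs (absent columns or
    NaN cells) are resolved per `missing_policy`:

    - ``"error"``: raise, listing the offending CpG ids;
    - ``"impute_stored_means"``: use the training probe means recorded in
      model provenance;
    - ``"impute_half"``: substitute beta = 0.5.
    """
    cpgs = model.cpg_ids()
    present = [c for c in cpgs if c in bm.values.columns]
    absent = [c for c in cpgs if c not in bm.values.columns]

    sub = bm.values[present].copy() if present else pd.DataFrame(index=bm.values.index)
    has_nan = bool(sub.isna().any().any()) if present else False
    if absent or has_nan:
        if missing_policy == "error":
            nan_cols = list(sub.columns[sub.isna().any()]) if present else []
            raise ValueError(
                f"model CpGs unresolvable in input: absent={absent[:10]} "
                f"nan_cells_in={nan_cols[:10]}"
            )
        if missing_policy == "impute_stored_means":
            means = model.provenance.get("probe_means")
            if means is None:
                raise ValueError("model provenance carries no stored probe means")
            fill = {c: float(means[c]) for c in cpgs if c in means}
            missing_means = [c for c in absent if c not in fill]
            if missing_means:
                raise ValueError(f"no stored mean for absent CpGs {missing_means[:10]}")
        elif missing_policy == "impute_half":
            fill = {c: 0.5 for c in cpgs}
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
        for c in absent:
            sub[c] = fill[c]
        sub = sub.fillna(pd.Series(fill))

    w = pd.Series(model.coefficients)
    dnam = model.intercept + (sub[cpgs] * w).sum(axis=1) if cpgs else pd.Series(
        model.intercept, index=bm.values.index, dtype=float
    )
    return PredictionResult.from_ages(
        dnam.to_numpy(dtype=float), bm.ages.to_numpy(), bm.sample_ids
    )


def accuracy_mad(pred: PredictionResult) -> float:
    """Median absolute prediction error |DNAm age - chronological age|, years."""
    if pred.n < 1:
        raise ValueError("empty prediction result")
    return float(np.median(np.abs(pred.residual.to_numpy())))


def precision_r(pred: PredictionResult) -> float:
    """Pearson correlation between DNAm age and chronological age."""
    if pred.n < 3:
        raise ValueError("need at least 3 samples for a correlation")
    x = pred.chronological_age.to_numpy()
    y = pred.dnam_age.to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: one series is constant")
    return float(stats.pearsonr(x, y).statistic)


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = 0.5*ln((1+r)/(1-r)) = arctanh(r)."""
    r = float(r)
    if not -1.0 < r < 1.0:
        raise ValueError(f"|r| must be < 1, got {r}")
    return float(np.arctanh(r))


def fisher_z_inverse(z: float) -> float:
    """Inverse Fisher transform, tanh(z)."""
    return float(np.tanh(z))


def bootstrap_r_ci(
    pred: PredictionResult,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for r on the Fisher-Z scale, back-transformed.

    Samples are resampled with replacement; degenerate resamples (either
    series constant) are redrawn. Z values are capped at
    arctanh(1 - 1e-12) so perfectly collinear resamples stay finite.
    """
    if pred.n < 10:
        raise ValueError("need at least 10 samples to bootstrap")
    rng = np.random.default_rng(seed)
    x = pred.chronological_age.to_numpy()
    y = pred.dnam_age.to_numpy()
    n = pred.n
    zs = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            xs, ys = x[idx], y[idx]
            if np.ptp(xs) > 0 and np.ptp(ys) > 0:
                break
            n_redrawn += 1
        r = np.corrcoef(xs, ys)[0, 1]
        r = np.clip(r, -(1 - 1e-12), 1 - 1e-12)  # cap so z stays finite
        zs[b] = np.arctanh(r)
    if n_redrawn:
        import warnings

        warnings.warn(f"redrew {n_redrawn} degenerate bootstrap resamples")
    lo, hi = np.quantile(zs, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(np.tanh(lo)), float(np.tanh(hi))


def _gcv_spline(x: np.ndarray, y: np.ndarray):
    """Cubic smoothing spline with GCV-chosen smoothness.

    Replicated x values are collapsed to weighted means (the spline
    routine needs strictly increasing x); fewer than 5 distinct x values
    fall back to a straight-line fit.
    """
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    ux, inv, counts = np.unique(xs, return_inverse=True, return_counts=True)
    ymeans = np.bincount(inv, weights=ys) / counts
    if len(ux) < 5:
        import warnings

        warnings.warn("fewer than 4 distinct x values; falling back to linear fit")
        slope, intercept = np.polyfit(x, y, 1)
        return lambda q: slope * np.asarray(q, dtype=float) + intercept
    spl = make_smoothing_spline(ux, ymeans, w=counts.astype(float))
    return spl


def compute_eaa(
    pred: PredictionResult,
    method: str = "linear",
    knot: float = 70.0,
    direction: str = "standard",
) -> EAAResult:
    """Epigenetic age acceleration under the chosen calibration.

    - ``linear``: residuals of OLS of DNAm age on chronological age.
    - ``piecewise_cubic``: residuals from a truncated-power cubic basis
      {age, age^2, age^3, (age - knot)_+^3} (continuous second
      derivative at the knot, default 70 years).
    - ``smoothing_spline``: residuals from a GCV cubic smoothing spline.

    ``direction="reverse"`` swaps the roles (chronological age regressed
    on DNAm age) for the alternative recalibration convention.
    """
    if method not in ("linear", "smoothing_spline", "piecewise_cubic"):
        raise ValueError(f"unknown EAA method {method!r}")
    age = pred.chronological_age.to_numpy()
    dnam = pred.dnam_age.to_numpy()
    if direction == "reverse":
        resp, cov = age, dnam
    else:
        resp, cov = dnam, age
    if method != "linear" and pred.n < 10:
        raise ValueError("spline calibrations need at least 10 samples")

    if method == "linear":
        slope, intercept = np.polyfit(cov, resp, 1)
        fitted = intercept + slope * cov
    elif method == "piecewise_cubic":
        if not cov.min() <= knot <= cov.max():
            import warnings

            warnings.warn(f"knot {knot} outside observed range "
                          f"[{cov.min():.1f}, {cov.max():.1f}]; fit proceeds")
        basis = np.column_stack([
            np.ones_like(cov), cov, cov ** 2, cov ** 3,
            np.clip(cov - knot, 0.0, None) ** 3,
        ])
        coef, *_ = np.linalg.lstsq(basis, resp, rcond=None)
        fitted = basis @ coef
    else:
        spl = _gcv_spline(cov, resp)
        fitted = np.asarray(spl(cov), dtype=float)

    eaa = resp - fitted
    if np.ptp(eaa) == 0 or np.ptp(age) == 0:
        diag = rank_diag = 0.0
    else:
        diag = float(np.corrcoef(eaa, age)[0, 1])
        rank_diag = float(stats.spearmanr(eaa, age).statistic)
    idx = pred.frame.index
    return EAAResult(
        eaa=pd.Series(eaa, index=idx, name="eaa"),
        method=method,
        knot=knot if method == "piecewise_cubic" else None,
        diagnostic_cor=diag,
        diagnostic_rank_cor=rank_diag,
        fitted=pd.Series(fitted, index=idx, name="fitted"),
    )


def compare_groups_eaa(
    eaa: EAAResult,
    groups,
    reference: str,
    level: float = 0.95,
) -> GroupComparison:
    """Welch two-sample comparison of EAA between two labelled groups.

    Returns the mean difference (comparison - reference) with the Welch
    t-test p-value and confidence interval.
    """
    groups = pd.Series(groups, index=eaa.eaa.index) if not isinstance(groups, pd.Series) else groups
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required, got {labels}; "
                         "run pairwise for more groups")
    if reference not in labels:
        raise ValueError(f"reference {reference!r} not among labels {labels}")
    comparison = next(l for l in labels if l != reference)
    a = eaa.eaa[groups == comparison].to_numpy()
    b = eaa.eaa[groups == reference].to_numpy()
    if min(len(a), len(b)) < 3:
        raise ValueError("each group needs at least 3 samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(confidence_level=level)
    return GroupComparison(
        reference=reference,
        comparison=comparison,
        mean_difference=float(a.mean() - b.mean()),
        ci=(float(ci.low), float(ci.high)),
        p_value=float(res.pvalue),
    )


def evaluate_predictions(
    pred: PredictionResult,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> EvaluationReport:
    """Precision (r with bootstrap CI), accuracy (MAD) and the regression
    line of DNAm age on chronological age."""
    r = precision_r(pred)
    ci = bootstrap_r_ci(pred, n_boot=n_boot, level=level, seed=seed)
    slope, intercept = np.polyfit(
        pred.chronological_age.to_numpy(), pred.dnam_age.to_numpy(), 1
    )
    return EvaluationReport(
        r=r,
        r_ci=ci,
        mad=accuracy_mad(pred),
        n=pred.n,
        regression_slope=float(slope),
        regression_intercept=float(intercept),
    )
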