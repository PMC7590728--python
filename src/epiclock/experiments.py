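"""Sample-size × probe-set comparison experiment.

Trains paired clocks — one on all EPIC probes, one restricted to the
autosomal 450K∩EPIC common set — on geometrically spaced random subsets
of a full training set, evaluates precision (r) and accuracy (MAD) on a
fixed test set, and summarizes the learning curves with GCV smoothing
splines (r on the Fisher-Z scale with back-transformed normal bands; MAD
untransformed). The paired design uses the identical subject subset for
both probe sets within each (size, replicate) cell, so per-cell
differences isolate the probe-set effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import accuracy_mad, precision_r, predict_age
from .io import BetaMatrix
from .qc import restrict_to_common
from .training import train_clock

__all__ = [
    "SubsampleDesign",
    "SubsampleResult",
    "geometric_size_grid",
    "run_subsample_experiment",
    "summarize_with_splines",
    "compare_platforms",
]

PROBE_SETS = ("epic_all", "common_450k")


@dataclass
class SubsampleDesign:
    """Grid of training sizes × replicates × probe sets."""

    sizes: list[int]
    replicates: int = 5
    probe_sets: tuple[str, ...] = PROBE_SETS
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if sorted(self.sizes) != list(self.sizes):
            raise ValueError("sizes must be ascending")
        unknown = set(self.probe_sets) - set(PROBE_SETS)
        if unknown:
            raise ValueError(f"unknown probe sets {sorted(unknown)}")


@dataclass
class SubsampleResult:
    """Records of (size, replicate, probe_set) → (r, mad, n CpGs) plus
    spline summaries per probe set and metric."""

    records: pd.DataFrame
    design: SubsampleDesign
    summaries: dict = field(default_factory=dict)


def geometric_size_grid(n_min: int, n_full: int, n_steps: int) -> list[int]:
    """Geometric training-size sequence, denser at the small end.

    sizes_k = round(n_min * (n_full / n_min)^(k / n_steps)), k = 0..n_steps-1,
    with ordinary nearest-integer rounding (half away from zero). Any
    duplicates produced by rounding over a tiny range are dropped with a
    warning.
    """
    if not 0 < n_min < n_full:
        raise ValueError("need 0 < n_min < n_full")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    ratio = n_full / n_min
    sizes = [int(np.floor(n_min * ratio ** (k / n_steps) + 0.5)) for k in range(n_steps)]
    dedup = sorted(set(sizes))
    if dedup != sizes:
        import warnings

        warnings.warn("rounding produced duplicate sizes; de-duplicated")
    return dedup


def _cell_seed(base_seed: int, size: int, replicate: int) -> int:
    """Deterministic, order-independent per-cell seed below 2^31."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(size, replicate))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_subsample_experiment(
    full_train: BetaMatrix,
    test: BetaMatrix,
    design: SubsampleDesign,
    train_params: dict | None = None,
) -> SubsampleResult:
    """Run the full (size × replicate × probe set) grid.

    Each cell draws a simple random subject subset (seed derived
    deterministically from ``base_seed``, size and replicate, so cells are
    reproducible in any execution order) and trains a clock per probe set
    on that identical subset; r and MAD are computed on the fixed test
    set. ``train_params`` is passed through to :func:`train_clock`.
    """
    train_params = dict(train_params or {})
    overlap = set(full_train.sample_ids) & set(test.sample_ids)
    if overlap:
        raise ValueError(f"test samples overlap training: {sorted(overlap)[:5]}")
    if design.sizes and design.sizes[-1] > full_train.n_samples:
        raise ValueError(
            f"largest size {design.sizes[-1]} exceeds training n={full_train.n_samples}"
        )

    restricted_cache = {
        "epic_all": (full_train, test),
    }
    if "common_450k" in design.probe_sets:
        restricted_cache["common_450k"] = (
            restrict_to_common(full_train),
            restrict_to_common(test),
        )

    ids = np.array(full_train.sample_ids)
    rows = []
    for size in design.sizes:
        for rep in range(design.replicates):
            seed = _cell_seed(design.base_seed, size, rep)
            rng = np.random.default_rng(seed)
            subset = sorted(rng.choice(ids, size, replace=False))
            subset_hash = hash(tuple(subset)) & 0xFFFFFFFF
            for probe_set in design.probe_sets:
                tr_full, te = restricted_cache[probe_set]
                tr = tr_full.select_samples(subset)
                model, _ = train_clock(
                    tr, seed=seed, probe_set_tag=probe_set, **train_params
                )
                pred = predict_age(model, te, missing_policy="error")
                rows.append({
                    "size": size,
                    "replicate": rep,
                    "probe_set": probe_set,
                    "r": precision_r(pred),
                    "mad": accuracy_mad(pred),
                    "n_selected_cpgs": model.n_cpgs,
                    "subset_hash": subset_hash,
                    "cell_seed": seed,
                })
    records = pd.DataFrame(rows)
    result = SubsampleResult(records=records, design=design)
    result.summaries = summarize_with_splines(result)
    return result


def _spline_band(x: np.ndarray, y: np.ndarray, grid: np.ndarray):
    """GCV smoothing spline of y on x with ±1.96·SE normal bands.

    Replicated x are collapsed to weighted means for the fit; the band
    half-width is 1.96 * residual_sd / sqrt(mean replicates per x), a
    normal approximation that collapses to zero as residual variance
    vanishes. Fewer than 4 distinct x values fall back to a linear fit.
    """
    from .evaluate import _gcv_spline

    fit = _gcv_spline(x, y)
    mean = np.asarray(fit(grid), dtype=float)
    resid = y - np.asarray(fit(x), dtype=float)
    m = len(x) / max(len(np.unique(x)), 1)
    se = resid.std(ddof=1) / np.sqrt(m) if len(x) > 1 else 0.0
    return mean, mean - 1.96 * se, mean + 1.96 * se


def summarize_with_splines(result: SubsampleResult, n_grid: int = 100) -> dict:
    """Learning-curve summaries per probe set.

    For r, records are Fisher-Z transformed, splined against size, and the
    curve and bands are back-transformed through tanh (bands therefore
    always lie in (-1, 1)); MAD is splined untransformed. Operates purely
    on the records, so re-summarizing a serialized result reproduces the
    curves bit-identically.
    """
    out: dict = {}
    rec = result.records
    for probe_set in sorted(rec["probe_set"].unique()):
        sub = rec[rec["probe_set"] == probe_set]
        sizes = sub["size"].to_numpy(dtype=float)
        n_distinct = len(np.unique(sizes))
        if n_distinct < 4:
            import warnings

            warnings.warn(
                f"{probe_set}: only {n_distinct} distinct sizes; spline falls back to linear"
            )
        grid = np.linspace(sizes.min(), sizes.max(), n_grid)
        z = np.arctanh(np.clip(sub["r"].to_numpy(), -(1 - 1e-12), 1 - 1e-12))
        zm, zlo, zhi = _spline_band(sizes, z, grid)
        mad = sub["mad"].to_numpy(dtype=float)
        mm, mlo, mhi = _spline_band(sizes, mad, grid)
        out[probe_set] = {
            "r": pd.DataFrame({
                "size": grid,
                "mean": np.tanh(zm),
                "low": np.tanh(zlo),
                "high": np.tanh(zhi),
            }),
            "mad": pd.DataFrame({
                "size": grid, "mean": mm, "low": mlo, "high": mhi,
            }),
        }
    return out


def compare_platforms(result: SubsampleResult, level: float = 0.95) -> pd.DataFrame:
    """Per-size paired differences (epic_all − common_450k) in r and MAD.

    Pairing relies on the identical subject subset per (size, replicate)
    cell; a mismatch in record structure raises. Returns one row per size
    with the mean difference and a t-based CI across replicates, plus a
    ``"all"`` row pooling every cell.
    """
    rec = result.records
    have = set(rec["probe_set"].unique())
    if not {"epic_all", "common_450k"} <= have:
        raise ValueError(f"need both probe sets, have {sorted(have)}")
    wide = rec.pivot_table(
        index=["size", "replicate"], columns="probe_set", values=["r", "mad", "subset_hash"]
    )
    if wide.isna().any().any():
        raise ValueError("unpaired records: some (size, replicate) cells lack a probe set")
    if not (wide[("subset_hash", "epic_all")] == wide[("subset_hash", "common_450k")]).all():
        raise ValueError("pairing violated: subject subsets differ across probe sets")
    dr = wide[("r", "epic_all")] - wide[("r", "common_450k")]
    dmad = wide[("mad", "epic_all")] - wide[("mad", "common_450k")]

    def _row(d_r: pd.Series, d_mad: pd.Series, label):
        n = len(d_r)
        out = {"size": label, "n_pairs": n,
               "delta_r_mean": float(d_r.mean()), "delta_mad_mean": float(d_mad.mean())}
        if n > 1 and d_r.std(ddof=1) > 0:
            tcrit = stats.t.ppf(0.5 + level / 2, n - 1)
            hw = tcrit * d_r.std(ddof=1) / np.sqrt(n)
            out["delta_r_low"], out["delta_r_high"] = out["delta_r_mean"] - hw, out["delta_r_mean"] + hw
        else:
            out["delta_r_low"] = out["delta_r_high"] = out["delta_r_mean"]
        return out

    rows = [
        _row(dr.xs(s, level="size"), dmad.xs(s, level="size"), s)
        for s in sorted(rec["size"].unique())
    ]
    rows.append(_row(dr, dmad, "all"))
    return pd.DataFrame(rows)
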