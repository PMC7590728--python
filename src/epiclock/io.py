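"""Domain containers and text I/O for beta matrices and clock coefficient files.

The pipeline currency is :class:`BetaMatrix` — a samples × CpGs grid of
methylation beta values in [0, 1] with aligned sample and probe metadata —
and :class:`ClockModel`, a sparse linear age predictor (intercept plus a
CpG → weight map). Both serialize to plain delimited text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "ClockModel",
    "QCReport",
    "BetaMatrixError",
    "ClockFileError",
    "INTERCEPT_TOKEN",
    "AUTOSOMES",
    "read_clock_coefficients",
    "write_clock_coefficients",
    "read_beta_matrix",
    "write_beta_matrix",
    "validate_beta_matrix",
    "days_to_years",
    "DAYS_PER_YEAR",
]

#: Reserved row id for the model intercept in coefficient files.
INTERCEPT_TOKEN = "(Intercept)"

#: Chromosome labels considered autosomal.
AUTOSOMES = frozenset(str(c) for c in range(1, 23))

#: Conversion constant when chronological age is supplied in days.
DAYS_PER_YEAR = 365.25

SAMPLE_META_COLUMNS = ("age", "sex", "group", "batch")
PROBE_META_COLUMNS = (
    "chromosome",
    "design_type",
    "cross_hybridizing",
    "snp_proximal",
    "on_450k",
    "on_epic",
)


class BetaMatrixError(ValueError):
    """Raised when a beta matrix violates its invariants."""


class ClockFileError(ValueError):
    """Raised on malformed clock coefficient files."""


def days_to_years(age_days: float | np.ndarray) -> float | np.ndarray:
    """Convert chronological age from days to years at 365.25 d/y."""
    return np.asarray(age_days, dtype=float) / DAYS_PER_YEAR


@dataclass
class BetaMatrix:
    """Samples × probes methylation levels with aligned metadata.

    Parameters
    ----------
    values
        DataFrame of beta values in [0, 1] (NaN = missing); index is
        ``sample_id``, columns are CpG ids.
    samples
        Per-sample metadata indexed by ``sample_id`` with columns
        ``age`` (years), ``sex``, ``group``, ``batch``.
    probes
        Per-probe metadata indexed by CpG id with columns ``chromosome``,
        ``design_type``, ``cross_hybridizing``, ``snp_proximal``,
        ``on_450k``, ``on_epic``.
    detection_p
        Optional detection p-value grid aligned with ``values``.
    provenance
        Free-form generation/processing record (e.g. the synthetic
        generator's configuration and ground-truth sidecar).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not self.samples.index.is_unique:
            raise BetaMatrixError("duplicate sample ids")
        if not self.probes.index.is_unique:
            raise BetaMatrixError("duplicate probe ids")
        if list(self.values.index) != list(self.samples.index):
            raise BetaMatrixError("value rows do not match sample metadata order")
        if list(self.values.columns) != list(self.probes.index):
            raise BetaMatrixError("value columns do not match probe metadata order")
        ages = self.samples["age"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ages)) or np.any(ages <= 0):
            raise BetaMatrixError("ages must be finite and > 0")
        vals = self.values.to_numpy()
        bad = (vals < 0) | (vals > 1)
        if np.any(bad):
            cells = self._offending_cells(bad)
            raise BetaMatrixError(f"beta values outside [0,1] at {cells}")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise BetaMatrixError("detection_p shape mismatch")
            self.detection_p = pd.DataFrame(
                self.detection_p.to_numpy(dtype=float),
                index=self.values.index,
                columns=self.values.columns,
            )

    def _offending_cells(self, bad: np.ndarray, limit: int = 5) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(bad)
        return [
            (str(self.values.index[i]), str(self.values.columns[j]))
            for i, j in list(zip(rows, cols))[:limit]
        ]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def ages(self) -> pd.Series:
        """Chronological ages in years, indexed by sample id."""
        return self.samples["age"].astype(float)

    def autosomal_mask(self) -> pd.Series:
        return self.probes["chromosome"].astype(str).isin(AUTOSOMES)

    def select_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        ids = list(sample_ids)
        return BetaMatrix(
            values=self.values.loc[ids],
            samples=self.samples.loc[ids],
            probes=self.probes,
            detection_p=None if self.detection_p is None else self.detection_p.loc[ids],
            provenance=dict(self.provenance),
        )

    def select_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        ids = list(probe_ids)
        return BetaMatrix(
            values=self.values[ids],
            samples=self.samples,
            probes=self.probes.loc[ids],
            detection_p=None if self.detection_p is None else self.detection_p[ids],
            provenance=dict(self.provenance),
        )


@dataclass
class ClockModel:
    """Sparse linear age predictor: DNAm age = intercept + Σ beta_cpg · weight.

    ``coefficients`` maps CpG id → weight in years per unit beta; zero
    weights are never stored. ``provenance`` records the training run
    (alpha, selected lambda, n_train, probe-set tag, seed, age unit,
    training probe means for imputation at prediction time).
    """

    intercept: float
    coefficients: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intercept = float(self.intercept)
        self.coefficients = {str(k): float(v) for k, v in self.coefficients.items()}
        if any(v == 0.0 for v in self.coefficients.values()):
            raise ClockFileError("stored coefficients must be nonzero")

    @property
    def n_cpgs(self) -> int:
        return len(self.coefficients)

    def cpg_ids(self) -> list[str]:
        return list(self.coefficients)


@dataclass
class QCReport:
    """Bookkeeping for probe/sample exclusions.

    ``excluded_per_criterion`` counts probes failing each criterion (a probe
    may fail several, so the counts can sum to more than the number
    removed); ``excluded_samples`` maps sample id → reason.
    """

    n_input_probes: int = 0
    n_surviving_probes: int = 0
    excluded_per_criterion: dict[str, int] = field(default_factory=dict)
    excluded_probe_ids: dict[str, list[str]] = field(default_factory=dict)
    excluded_samples: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.excluded_per_criterion.values()):
            raise ValueError("exclusion counts must be non-negative")

    def summary(self) -> str:
        lines = [
            f"input probes: {self.n_input_probes}",
            f"surviving probes: {self.n_surviving_probes}",
        ]
        for crit, n in sorted(self.excluded_per_criterion.items()):
            lines.append(f"excluded[{crit}]: {n}")
        for sid, reason in self.excluded_samples.items():
            lines.append(f"excluded sample {sid}: {reason}")
        lines.extend(self.notes)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Clock coefficient files: CSV, header "CpG,Coefficient", intercept row first
# under the reserved token "(Intercept)".
# ---------------------------------------------------------------------------

def read_clock_coefficients(path) -> ClockModel:
    """Parse a clock coefficient CSV into a :class:`ClockModel`.

    The file must contain exactly one record whose id equals
    ``(Intercept)``; every other row becomes a coefficient. Zero-valued
    rows are dropped with a warning (they carry no information for the
    linear predictor).
    """
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ClockFileError(f"{path}: expected two columns (CpG, Coefficient)")
    ids = df.iloc[:, 0].astype(str)
    try:
        weights = df.iloc[:, 1].astype(float)
    except (TypeError, ValueError) as exc:
        raise ClockFileError(f"{path}: non-numeric coefficient: {exc}") from exc
    if not np.all(np.isfinite(weights.to_numpy())):
        raise ClockFileError(f"{path}: non-finite coefficient")
    is_int = ids == INTERCEPT_TOKEN
    if int(is_int.sum()) != 1:
        raise ClockFileError(
            f"{path}: expected exactly one {INTERCEPT_TOKEN!r} record, found {int(is_int.sum())}"
        )
    intercept = float(weights[is_int].iloc[0])
    cpg_ids = ids[~is_int]
    if cpg_ids.duplicated().any():
        dups = sorted(cpg_ids[cpg_ids.duplicated()].unique())
        raise ClockFileError(f"{path}: duplicate CpG ids {dups}")
    coefs: dict[str, float] = {}
    n_zero = 0
    for cpg, w in zip(cpg_ids, weights[~is_int]):
        if w == 0.0:
            n_zero += 1
        else:
            coefs[cpg] = float(w)
    if n_zero:
        warnings.warn(f"{path}: dropped {n_zero} zero-valued coefficient rows")
    return ClockModel(intercept=intercept, coefficients=coefs)


def write_clock_coefficients(model: ClockModel, path) -> None:
    """Write a coefficient CSV (intercept first) at full decimal precision."""
    rows = [(INTERCEPT_TOKEN, model.intercept)]
    rows.extend(model.coefficients.items())
    with open(path, "w") as fh:
        fh.write("CpG,Coefficient\n")
        for cpg, w in rows:
            fh.write(f"{cpg},{w!r}\n")  # repr round-trips float64 exactly


# ---------------------------------------------------------------------------
# Beta matrix: TSV, samples as rows (first column `sample_id`), probes as
# columns; companion TSVs for sample and probe metadata; optional aligned
# detection-p TSV.
# ---------------------------------------------------------------------------

def read_beta_matrix(
    path,
    sample_meta_path,
    probe_meta_path,
    detection_p_path=None,
) -> BetaMatrix:
    """Read the TSV trio (values, sample meta, probe meta) into a BetaMatrix.

    Rows and columns are reordered to metadata order, so the result is
    independent of on-disk ordering given identical id sets.
    """
    values = pd.read_csv(path, sep="\t", index_col="sample_id")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    samples = pd.read_csv(sample_meta_path, sep="\t", index_col="sample_id")
    samples.index = samples.index.astype(str)
    probes = pd.read_csv(probe_meta_path, sep="\t", index_col="cpg_id")
    probes.index = probes.index.astype(str)

    if set(values.index) != set(samples.index):
        raise BetaMatrixError("sample ids in matrix and metadata differ as sets")
    if set(values.columns) != set(probes.index):
        raise BetaMatrixError("probe ids in matrix and metadata differ as sets")
    values = values.loc[samples.index, probes.index]

    detection_p = None
    if detection_p_path is not None:
        detection_p = pd.read_csv(detection_p_path, sep="\t", index_col="sample_id")
        detection_p.index = detection_p.index.astype(str)
        detection_p.columns = detection_p.columns.astype(str)
        detection_p = detection_p.loc[samples.index, probes.index]
    return BetaMatrix(values=values, samples=samples, probes=probes, detection_p=detection_p)


def write_beta_matrix(bm: BetaMatrix, prefix) -> dict[str, str]:
    """Write the TSV trio (plus detection-p grid if present) under `prefix`.

    Returns the mapping of role → written path.
    """
    paths = {
        "values": f"{prefix}_betas.tsv",
        "samples": f"{prefix}_samples.tsv",
        "probes": f"{prefix}_probes.tsv",
    }
    bm.values.to_csv(paths["values"], sep="\t", index_label="sample_id")
    bm.samples.to_csv(paths["samples"], sep="\t", index_label="sample_id")
    bm.probes.to_csv(paths["probes"], sep="\t", index_label="cpg_id")
    if bm.detection_p is not None:
        paths["detection_p"] = f"{prefix}_detection_p.tsv"
        bm.detection_p.to_csv(paths["detection_p"], sep="\t", index_label="sample_id")
    return paths


def validate_beta_matrix(bm: BetaMatrix) -> QCReport:
    """Report missingness and unusable probes; never raises."""
    vals = bm.values.to_numpy()
    missing = np.isnan(vals)
    report = QCReport(
        n_input_probes=bm.n_probes,
        n_surviving_probes=bm.n_probes,
        excluded_per_criterion={"missing_cells": int(missing.sum())},
    )
    probe_missing = missing.sum(axis=0)
    sample_missing = missing.sum(axis=1)
    report.excluded_per_criterion["probes_with_missing"] = int((probe_missing > 0).sum())
    report.excluded_per_criterion["samples_with_missing"] = int((sample_missing > 0).sum())
    all_missing = np.nonzero(probe_missing == bm.n_samples)[0]
    if all_missing.size:
        ids = [bm.probe_ids[i] for i in all_missing]
        report.excluded_probe_ids["all_missing"] = ids
        report.notes.append(f"unusable (all-missing) probes: {ids}")
    return report
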