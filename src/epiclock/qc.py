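"""Probe and sample exclusion rules for methylation arrays.

Implements the standard clock-building QC cascade: drop sex-chromosome,
cross-hybridizing and SNP-proximal probes and probes with high detection
p-values; union per-batch exclusions across batches; restrict to the
autosomal 450K∩EPIC common set; and flag samples with extreme epigenetic
age acceleration.

All thresholds use strict inequalities (a probe fails detection at
p > threshold; a sample is an outlier at |EAA| > threshold).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence, Set

import numpy as np

from .io import BetaMatrix, QCReport

__all__ = [
    "PROBE_CRITERIA",
    "filter_probes",
    "union_batch_exclusions",
    "restrict_to_common",
    "restrict_to_autosomes",
    "exclude_outlier_samples",
]

#: Recognized probe-exclusion criteria: sex chromosome (SC), cross-
#: hybridizing (CH), detection p-value (DP), SNP-proximal (SNP).
PROBE_CRITERIA = frozenset({"sex_chromosome", "cross_hybridizing", "detection_p", "snp_proximal"})

_SHORT = {
    "sex_chromosome": "SC",
    "cross_hybridizing": "CH",
    "detection_p": "DP",
    "snp_proximal": "SNP",
}


def filter_probes(
    bm: BetaMatrix,
    criteria: Iterable[str] = PROBE_CRITERIA,
    detection_threshold: float = 0.01,
    detection_sample_fraction: float = 0.0,
) -> tuple[BetaMatrix, QCReport]:
    """Remove probes failing any requested criterion.

    The detection rule removes a probe when the fraction of samples with
    detection p > ``detection_threshold`` strictly exceeds
    ``detection_sample_fraction`` — the default 0 is the strictest
    reading: any single failing cell removes the probe.

    The surviving probe set is independent of the order the criteria are
    given in (each criterion is evaluated on the full input).
    """
    criteria = set(criteria)
    unknown = criteria - PROBE_CRITERIA
    if unknown:
        raise ValueError(f"unknown criteria: {sorted(unknown)}")
    if "detection_p" in criteria and bm.detection_p is None:
        raise ValueError("detection_p criterion requested but no detection-p grid present")

    fails: dict[str, np.ndarray] = {}
    if "sex_chromosome" in criteria:
        fails["sex_chromosome"] = (~bm.autosomal_mask()).to_numpy()
    if "cross_hybridizing" in criteria:
        fails["cross_hybridizing"] = bm.probes["cross_hybridizing"].to_numpy(dtype=bool)
    if "snp_proximal" in criteria:
        fails["snp_proximal"] = bm.probes["snp_proximal"].to_numpy(dtype=bool)
    if "detection_p" in criteria:
        frac_failing = (bm.detection_p.to_numpy() > detection_threshold).mean(axis=0)
        fails["detection_p"] = frac_failing > detection_sample_fraction

    any_fail = np.zeros(bm.n_probes, dtype=bool)
    for mask in fails.values():
        any_fail |= mask
    keep_ids = [pid for pid, bad in zip(bm.probe_ids, any_fail) if not bad]

    report = QCReport(
        n_input_probes=bm.n_probes,
        n_surviving_probes=len(keep_ids),
        excluded_per_criterion={
            _SHORT[c]: int(mask.sum()) for c, mask in fails.items()
        },
        excluded_probe_ids={
            _SHORT[c]: [pid for pid, bad in zip(bm.probe_ids, mask) if bad]
            for c, mask in fails.items()
        },
    )
    for c in PROBE_CRITERIA - criteria:
        report.excluded_per_criterion.setdefault(_SHORT[c], 0)
    return bm.select_probes(keep_ids), report


def union_batch_exclusions(per_batch_excluded: Sequence[Set[str]]) -> set[str]:
    """Probes excluded in any batch are removed from all batches."""
    out: set[str] = set()
    for batch_set in per_batch_excluded:
        out |= set(batch_set)
    return out


def restrict_to_common(bm: BetaMatrix) -> BetaMatrix:
    """Keep exactly the autosomal probes present on both 450K and EPIC."""
    keep = (
        bm.probes["on_450k"].astype(bool)
        & bm.probes["on_epic"].astype(bool)
        & bm.autosomal_mask()
    )
    return bm.select_probes([pid for pid, k in zip(bm.probe_ids, keep) if k])


def restrict_to_autosomes(bm: BetaMatrix) -> BetaMatrix:
    """Keep autosomal probes only (order preserved)."""
    keep = bm.autosomal_mask()
    if not keep.any():
        warnings.warn("no autosomal probes remain after restriction")
    return bm.select_probes([pid for pid, k in zip(bm.probe_ids, keep) if k])


def exclude_outlier_samples(eaa, eaa_threshold: float = 15.0) -> set[str]:
    """Samples whose absolute epigenetic age acceleration exceeds the threshold.

    ``eaa`` is a per-sample mapping/Series of linear-calibrated EAA in
    years (e.g. ``EAAResult.eaa``); the comparison is strict
    (|EAA| > threshold fails).
    """
    eaa = getattr(eaa, "eaa", eaa)  # accept an EAAResult directly
    import pandas as pd

    series = pd.Series(dict(eaa)) if not isinstance(eaa, pd.Series) else eaa
    return set(series.index[series.abs() > eaa_threshold].astype(str))
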