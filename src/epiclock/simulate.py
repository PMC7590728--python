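"""Synthetic methylation cohorts with planted age signal.

The generator emulates the statistical structure an adult blood-based
epigenetic clock assumes: a minority of age-informative CpGs whose mean
methylation drifts linearly with age on the logit scale, beta-distributed
measurement noise around those means, array-style probe annotations
(450K/EPIC membership, chromosome, cross-hybridization and SNP-proximity
flags), optional batch structure and an optional epigenetic-age offset
planted in a labelled subgroup.

Generative model, for sample j with age a_j (standardized z_j) and probe i:

    logit mean  m_ij = mu_i + b_i * z_j            (causal probes)
                m_ij = mu_i                        (non-causal probes)
                + batch offset (+ subgroup shift on causal probes)
    observed    beta_ij ~ Beta( sigmoid(m_ij)*phi, (1-sigmoid(m_ij))*phi )

so betas never leave (0, 1) and the per-probe noise scale is governed by
the concentration phi (sd ≈ 0.05 at mid-range for the default phi = 50).

The subgroup shift of s years is implemented exactly as "being s years
older on the causal axis": every causal probe's logit mean gains
b_i * s / sd(age), so any consistent clock reads the subgroup as shifted
by ≈ s years of DNAm age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import BetaMatrix

__all__ = ["SyntheticConfig", "generate_cohort", "split_train_test"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SyntheticConfig:
    """Configuration of a synthetic adult-blood cohort.

    Defaults emulate an adult cohort spanning 18–88 years measured on an
    EPIC-like array: ~45% of probes EPIC-only, a small sex-chromosome
    fraction, array-typical flag rates, beta noise with concentration 50.

    Parameters
    ----------
    n_samples, n_probes, n_causal
        Cohort and array size; number of age-informative CpGs.
    age_range
        (min, max) chronological age in years.
    age_distribution
        ``"uniform"`` over ``age_range``, or ``"mixture"`` — a
        mixture of two uniforms, U(min, 46) with weight 0.75 and
        U(46, max) with weight 0.25, mimicking a pregnancy cohort with an
        older extension.
    effect_sd
        Spread of per-causal-CpG age slopes, in logits per standardized-age
        unit (slopes drawn N(0, effect_sd²), sign random).
    baseline_spread
        Spread of probe logit baselines mu_i ~ N(0, baseline_spread²).
    precision
        Beta-noise concentration phi (> 0); larger = less noise.
    frac_epic_only
        Fraction of probes flagged on_epic but not on_450k.
    causal_common_fraction
        Fraction of causal CpGs placed in the 450K∩EPIC common set
        (the rest are EPIC-only).
    group_shift_years
        Epigenetic-age offset (years) planted in the subgroup labelled
        ``"shifted"``; 0 disables the subgroup.
    group_fraction
        Fraction of samples in the shifted subgroup when a shift is set.
    batch_count, batch_sd
        Number of batches and the sd of per-(batch, probe) logit offsets.
    sex_chromosome_fraction, cross_hybridizing_fraction, snp_proximal_fraction
        Probe-annotation rates; causal probes are always autosomal and
        unflagged so QC cannot silently destroy the planted signal.
    detection_fail_rate
        Per-cell probability that the detection p-value is drawn above
        0.01 (failed measurement); the rest are drawn below it.
    seed
        Random seed; identical configs produce bit-identical cohorts.
    """

    n_samples: int = 400
    n_probes: int = 2000
    n_causal: int = 100
    age_range: tuple[float, float] = (18.0, 88.0)
    age_distribution: str = "uniform"
    effect_sd: float = 0.4
    baseline_spread: float = 1.5
    precision: float = 50.0
    frac_epic_only: float = 0.45
    causal_common_fraction: float = 0.5
    group_shift_years: float = 0.0
    group_fraction: float = 0.5
    batch_count: int = 1
    batch_sd: float = 0.0
    sex_chromosome_fraction: float = 0.025
    cross_hybridizing_fraction: float = 0.03
    snp_proximal_fraction: float = 0.02
    detection_fail_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_causal > self.n_probes:
            raise ValueError("n_causal must not exceed n_probes")
        if self.precision <= 0:
            raise ValueError("precision (phi) must be > 0")
        if not (self.age_range[0] > 0 and self.age_range[1] > self.age_range[0]):
            raise ValueError("age_range must be increasing and positive")
        if self.age_distribution not in ("uniform", "mixture"):
            raise ValueError("age_distribution must be 'uniform' or 'mixture'")
        for name in (
            "frac_epic_only",
            "causal_common_fraction",
            "group_fraction",
            "sex_chromosome_fraction",
            "cross_hybridizing_fraction",
            "snp_proximal_fraction",
            "detection_fail_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.batch_count < 1:
            raise ValueError("batch_count must be >= 1")


def _draw_ages(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.age_range
    if cfg.age_distribution == "uniform":
        return rng.uniform(lo, hi, cfg.n_samples)
    knee = min(46.0, hi)
    young = rng.uniform(lo, knee, cfg.n_samples)
    old = rng.uniform(knee, hi, cfg.n_samples)
    is_old = rng.random(cfg.n_samples) < 0.25
    return np.where(is_old, old, young)


def generate_cohort(cfg: SyntheticConfig) -> BetaMatrix:
    """Generate a cohort under `cfg`; deterministic given ``cfg.seed``.

    The returned matrix carries a ground-truth sidecar in
    ``provenance["ground_truth"]`` (causal CpG ids and their logit slopes)
    and the full config in ``provenance["config"]``; training code must not
    look at either.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_probes

    ages = _draw_ages(cfg, rng)
    age_sd = ages.std()
    z = (ages - ages.mean()) / age_sd

    sample_ids = [f"S{j:05d}" for j in range(n)]
    sexes = rng.choice(["female", "male"], n)
    batches = np.array([f"batch{b}" for b in rng.integers(0, cfg.batch_count, n)])
    if cfg.group_shift_years != 0.0:
        shifted = rng.random(n) < cfg.group_fraction
        groups = np.where(shifted, "shifted", "reference")
    else:
        shifted = np.zeros(n, dtype=bool)
        groups = np.full(n, "reference")

    # Probe annotations. Causal probes are drawn from autosomal, unflagged
    # probes so the QC cascade cannot remove the planted signal.
    probe_ids = [f"cg{i:07d}" for i in range(p)]
    chrom = np.array([str(c) for c in rng.integers(1, 23, p)], dtype=object)
    n_sex = int(round(cfg.sex_chromosome_fraction * p))
    sex_idx = rng.choice(p, n_sex, replace=False) if n_sex else np.array([], dtype=int)
    chrom[sex_idx] = rng.choice(["X", "Y"], n_sex)
    cross = rng.random(p) < cfg.cross_hybridizing_fraction
    snp = rng.random(p) < cfg.snp_proximal_fraction
    epic_only = rng.random(p) < cfg.frac_epic_only
    design = rng.choice(["I", "II"], p, p=[0.15, 0.85])

    clean = np.nonzero(
        np.isin(chrom.astype(str), list("123456789") + [str(c) for c in range(10, 23)])
        & ~cross
        & ~snp
    )[0]
    clean_common = clean[~epic_only[clean]]
    clean_epic_only = clean[epic_only[clean]]
    n_causal_common = int(round(cfg.causal_common_fraction * cfg.n_causal))
    n_causal_epic = cfg.n_causal - n_causal_common
    if len(clean_common) < n_causal_common or len(clean_epic_only) < n_causal_epic:
        raise ValueError("not enough clean probes to place causal CpGs; "
                         "lower flag fractions or n_causal")
    causal_idx = np.concatenate([
        rng.choice(clean_common, n_causal_common, replace=False),
        rng.choice(clean_epic_only, n_causal_epic, replace=False),
    ])
    causal_idx.sort()

    mu = rng.normal(0.0, cfg.baseline_spread, p)
    slopes = np.zeros(p)
    slopes[causal_idx] = rng.normal(0.0, cfg.effect_sd, len(causal_idx))

    m = mu[None, :] + np.outer(z, slopes)
    if cfg.batch_count > 1 and cfg.batch_sd > 0:
        batch_labels = sorted(set(batches))
        offsets = rng.normal(0.0, cfg.batch_sd, (len(batch_labels), p))
        bidx = np.array([batch_labels.index(b) for b in batches])
        m = m + offsets[bidx]
    if cfg.group_shift_years != 0.0:
        # shift_z standardized-age units ≡ group_shift_years years of DNAm age
        shift_z = cfg.group_shift_years / age_sd
        m = m + np.outer(shifted.astype(float) * shift_z, slopes)

    mean_beta = np.clip(_sigmoid(m), 1e-12, 1 - 1e-12)
    phi = cfg.precision
    betas = rng.beta(mean_beta * phi, (1.0 - mean_beta) * phi)
    betas = np.clip(betas, 1e-12, 1 - 1e-12)

    fail = rng.random((n, p)) < cfg.detection_fail_rate
    detection_p = np.where(
        fail,
        rng.uniform(0.011, 1.0, (n, p)),
        rng.uniform(0.0, 0.009, (n, p)),
    )

    samples = pd.DataFrame(
        {"age": ages, "sex": sexes, "group": groups, "batch": batches},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    probes = pd.DataFrame(
        {
            "chromosome": chrom.astype(str),
            "design_type": design,
            "cross_hybridizing": cross,
            "snp_proximal": snp,
            "on_450k": ~epic_only,
            "on_epic": np.ones(p, dtype=bool),
        },
        index=pd.Index(probe_ids, name="cpg_id"),
    )
    ground_truth = pd.DataFrame(
        {
            "cpg_id": [probe_ids[i] for i in causal_idx],
            "slope_logit_per_sd_age": slopes[causal_idx],
        }
    )
    provenance = {
        "generator": "epiclock.simulate.generate_cohort",
        "config": asdict(cfg),
        "age_sd": float(age_sd),
        "age_mean": float(ages.mean()),
        "group_shift_logit_per_sd": (
            float(cfg.group_shift_years / age_sd) if cfg.group_shift_years else 0.0
        ),
        "ground_truth": ground_truth,
    }
    return BetaMatrix(
        values=pd.DataFrame(betas, index=samples.index, columns=probes.index),
        samples=samples,
        probes=probes,
        detection_p=pd.DataFrame(detection_p, index=samples.index, columns=probes.index),
        provenance=provenance,
    )


def split_train_test(
    bm: BetaMatrix, test_fraction: float, seed: int
) -> tuple[BetaMatrix, BetaMatrix]:
    """Random disjoint, exhaustive sample split; probe set unchanged.

    Returns ``(train, test)`` with ``round(n * test_fraction)`` test samples.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.array(bm.sample_ids)
    n_test = int(round(len(ids) * test_fraction))
    n_test = min(max(n_test, 1), len(ids) - 1)
    perm = rng.permutation(len(ids))
    test_ids = ids[perm[:n_test]]
    train_ids = ids[perm[n_test:]]
    return bm.select_samples(sorted(train_ids)), bm.select_samples(sorted(test_ids))
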