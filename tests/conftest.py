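import numpy as np
import pandas as pd
import pytest

from epiclock.io import BetaMatrix


def make_beta_matrix(
    values: np.ndarray,
    ages=None,
    chromosomes=None,
    cross_hybridizing=None,
    snp_proximal=None,
    on_450k=None,
    detection_p=None,
    groups=None,
) -> BetaMatrix:
    """Hand-built small matrix with explicit per-probe annotations."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = [f"S{i}" for i in range(n)]
    probe_ids = [f"cg{j:03d}" for j in range(p)]
    samples = pd.DataFrame(
        {
            "age": ages if ages is not None else np.linspace(20, 60, n),
            "sex": ["female"] * n,
            "group": groups if groups is not None else ["reference"] * n,
            "batch": ["batch0"] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    probes = pd.DataFrame(
        {
            "chromosome": chromosomes if chromosomes is not None else ["1"] * p,
            "design_type": ["II"] * p,
            "cross_hybridizing": cross_hybridizing if cross_hybridizing is not None else [False] * p,
            "snp_proximal": snp_proximal if snp_proximal is not None else [False] * p,
            "on_450k": on_450k if on_450k is not None else [True] * p,
            "on_epic": [True] * p,
        },
        index=pd.Index(probe_ids, name="cpg_id"),
    )
    det = None
    if detection_p is not None:
        det = pd.DataFrame(np.asarray(detection_p, dtype=float),
                           index=samples.index, columns=probes.index)
    return BetaMatrix(
        values=pd.DataFrame(values, index=samples.index, columns=probes.index),
        samples=samples,
        probes=probes,
        detection_p=det,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate synthetic cohort shared by training/evaluation tests."""
    from epiclock.simulate import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(n_samples=240, n_probes=600, n_causal=60,
                          effect_sd=0.4, precision=50.0, seed=3)
    return generate_cohort(cfg)
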