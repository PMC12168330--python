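import numpy as np
import pandas as pd
import pytest

from plasmanet.simulate import study_cohort_config, generate_cohort
from plasmanet.qc import (
    apply_lod_mask,
    filter_proteins,
    remove_outlier_samples,
    bootstrap_covariate_adjust,
)


@pytest.fixture(scope="session")
def study_cohort():
    """One study-structure cohort (9 planted modules, 3 outliers) with truth."""
    cfg = study_cohort_config(seed=11)
    matrix, meta, qc, traits, gt = generate_cohort(cfg)
    return {"config": cfg, "matrix": matrix, "meta": meta, "qc": qc,
            "traits": traits, "truth": gt}


@pytest.fixture(scope="session")
def clean_cohort(study_cohort):
    """The same cohort after the full QC chain (light bootstrap for speed)."""
    m = apply_lod_mask(study_cohort["matrix"], study_cohort["qc"])
    m, prot_report = filter_proteins(m, study_cohort["qc"])
    m, samp_report = remove_outlier_samples(m)
    meta = study_cohort["meta"].loc[m.index]
    adjusted, coefs = bootstrap_covariate_adjust(m, meta, n_boot=25, seed=7)
    return {**study_cohort, "clean": adjusted, "meta_clean": meta,
            "prot_report": prot_report, "samp_report": samp_report, "coefs": coefs}


@pytest.fixture(scope="session")
def network_model(clean_cohort):
    from plasmanet.network import build_network
    return build_network(clean_cohort["clean"])


def two_block_matrix(seed=0, n=40, block=30, signal=0.7):
    """Samples x proteins with two independent latent-factor blocks."""
    rng = np.random.default_rng(seed)
    f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
    X = np.empty((n, 2 * block))
    X[:, :block] = np.sqrt(signal) * f1[:, None] + np.sqrt(1 - signal) * rng.standard_normal((n, block))
    X[:, block:] = np.sqrt(signal) * f2[:, None] + np.sqrt(1 - signal) * rng.standard_normal((n, block))
    return pd.DataFrame(X, index=[f"S{i}" for i in range(n)],
                        columns=[f"P{j}" for j in range(2 * block)])
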