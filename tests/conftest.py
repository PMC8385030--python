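import numpy as np
import pytest

from rhmkit import SimConfig, compute_grm, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """A small fully-null ascertained cohort (no genetic effects), shared
    across tests that only need calibrated noise."""
    cfg = SimConfig(
        n_cases=105,
        n_controls=195,
        n_snps_per_chrom=(500,),
        maf_range=(0.05, 0.5),
        prevalence=0.35,
        seed=1,
    )
    geno, pheno, truth = simulate_cohort(cfg)
    return geno, pheno, truth


@pytest.fixture(scope="session")
def null_design(null_cohort):
    geno, pheno, _ = null_cohort
    y = pheno["PHENO"].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(y)), pheno["SEX"].to_numpy(float), pheno["ARRAY"].to_numpy(float)]
    )
    return y, X


@pytest.fixture(scope="session")
def null_grm(null_cohort):
    geno, _, _ = null_cohort
    return compute_grm(geno)
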