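import numpy as np
import pandas as pd
import pytest

from epilogic.datasets import CohortDataset, SNPMeta


def make_cohort(genotypes, phenotype, snp_ids=None, covariates=None) -> CohortDataset:
    """Build a CohortDataset from plain arrays with generated subject ids."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, p = genotypes.shape
    snp_ids = snp_ids or [f"rs{j + 1:03d}" for j in range(p)]
    cov = pd.DataFrame(covariates) if covariates is not None else pd.DataFrame()
    return CohortDataset(
        subjects=[f"S{i + 1:04d}" for i in range(n)],
        phenotype=np.asarray(phenotype, dtype=np.int8),
        genotypes=genotypes,
        snps=[SNPMeta(snp_id=s) for s in snp_ids],
        covariates=cov,
    )


def hwe_genotypes(rng, n, mafs):
    q = np.asarray(mafs, dtype=float)
    return ((rng.random((n, q.size)) < q).astype(np.int8)
            + (rng.random((n, q.size)) < q).astype(np.int8))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_cohort(rng):
    """200 subjects x 4 SNPs, balanced classes, no missing data."""
    g = hwe_genotypes(rng, 200, [0.2, 0.3, 0.4, 0.25])
    y = np.r_[np.ones(90, dtype=np.int8), np.zeros(110, dtype=np.int8)]
    rng.shuffle(y)
    return make_cohort(g, y, covariates={"BMI": rng.normal(26, 4, 200)})
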