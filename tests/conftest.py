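import numpy as np
import pytest

from generank import (
    RunConfig,
    SyntheticTruth,
    ld_matrix,
    residualized_fast_gwas,
    simulate_genotypes,
    simulate_phenotypes,
)
from generank.synth import LDBlockSpec, make_annotation_and_sets


@pytest.fixture(scope="session")
def geno_small():
    """400 individuals x 200 SNPs (40 AR(1) blocks of 5)."""
    spec = LDBlockSpec(n_snps_per_block=5, n_blocks=40, within_block_rho=0.8)
    return simulate_genotypes(spec, 400, seed=11)


@pytest.fixture(scope="session")
def annotation_sets(geno_small):
    return make_annotation_and_sets(
        geno_small, genes_per_chrom=20, set_sizes=[3, 5, 8], seed=11, gene_span_snps=4
    )


@pytest.fixture(scope="session")
def pheno_null(geno_small):
    return simulate_phenotypes(geno_small, SyntheticTruth(), seed=12)


@pytest.fixture(scope="session")
def assoc_null(geno_small, pheno_null):
    return residualized_fast_gwas(geno_small, pheno_null, RunConfig())


@pytest.fixture(scope="session")
def ld_small(geno_small):
    return ld_matrix(geno_small)


def random_corr(rng: np.random.Generator, k: int) -> np.ndarray:
    """Random well-conditioned correlation matrix."""
    a = rng.standard_normal((k + 5, k))
    r = np.corrcoef(a.T)
    return np.clip(r, -1.0, 1.0)
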