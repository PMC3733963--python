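import numpy as np
import pytest

from locepi.synthetic_data import (
    PhenoModelSpec,
    fig2_block,
    simulate_genotypes,
    simulate_phenotype,
    unlinked_blocks,
)


@pytest.fixture(scope="session")
def fig2_population():
    """Large noiseless sample from the haplotype-masked recessive model.

    100k individuals, two MAF-0.5 SNPs in linkage equilibrium, untyped
    recessive variant on the minor-minor haplotype giving affected
    individuals trait value 2.  Shared across tests (read-only).
    """
    geno = simulate_genotypes([fig2_block()], 100_000, seed=20_001)
    spec = PhenoModelSpec(causal_haplotype_effect=2.0, noise_sd=0.0)
    pheno, truth = simulate_phenotype(geno, spec, seed=20_002)
    return geno, pheno["trait"].to_numpy(), truth


@pytest.fixture(scope="session")
def null_panel():
    """500 samples x 600 unlinked MAF-0.3 SNPs plus an unrelated N(0,1) trait."""
    geno = simulate_genotypes(unlinked_blocks(600, maf=0.3), 500, seed=30_001)
    y = np.random.default_rng(30_002).standard_normal(500)
    return geno, y
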