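import numpy as np
import pandas as pd
import pytest

from gwasplus import famsim, fgls

SMALL_COUNTS = {"MZ": 30, "DZ": 20, "ADOPT2": 8, "BIO2": 8, "MIXED": 5, "STEP": 4}

#: full-membership presence map (every family complete) for fixtures where
#: partial families would only add noise
FULL_PRESENCE = {
    t: {"parent": 1.0, "offspring2": 1.0}
    for t in ("MZ", "DZ", "ADOPT2", "BIO2", "MIXED")
}


@pytest.fixture(scope="session")
def small_pedigree():
    return famsim.simulate_families(SMALL_COUNTS, seed=101)


@pytest.fixture(scope="session")
def small_genotypes(small_pedigree):
    return famsim.simulate_genotypes(
        small_pedigree, n_snps=800, ld_block_size=5, missing_rate=0.002, seed=102
    )


@pytest.fixture(scope="session")
def small_phenotype(small_pedigree, small_genotypes):
    arch = famsim.TraitArchitecture(n_causal=200, h2_target=0.4, c2_target=0.2)
    return famsim.simulate_phenotype(small_pedigree, small_genotypes, arch, seed=103)


@pytest.fixture(scope="session")
def small_covfit(small_phenotype, small_pedigree):
    return fgls.fit_covariates_only(small_phenotype, small_pedigree)


@pytest.fixture(scope="session")
def full_pedigree():
    """Complete four-member families (plus step singletons)."""
    return famsim.simulate_families(
        {"MZ": 25, "DZ": 20, "ADOPT2": 10, "BIO2": 10, "MIXED": 5, "STEP": 5},
        seed=201,
        presence=FULL_PRESENCE,
    )


def toy_genotype_matrix(values, chrom=None, pos=None, typed=True, ids=None):
    """Small helper to wrap a raw array as a GenotypeMatrix."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    meta = pd.DataFrame(
        {
            "snp_id": [f"s{j + 1}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
            "a1": "A",
            "a2": "G",
            "typed": typed,
            "imputation_r2": 1.0,
            "maf": np.nanmean(values, axis=0) / 2.0,
        }
    )
    if ids is None:
        ids = np.array([f"i{k + 1}" for k in range(n)])
    return famsim.GenotypeMatrix(values, np.asarray(ids), meta)
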