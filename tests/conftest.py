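import logging

import numpy as np
import pytest

import outbredgwas as og
from outbredgwas.genotypes import GenotypeMatrix

logging.getLogger("outbredgwas").setLevel(logging.ERROR)


def make_matrix(geno, chrom=None, pos=None, snp_ids=None, sample_ids=None):
    """Build a GenotypeMatrix from a raw (n, m) array with defaults."""
    geno = np.asarray(geno)
    n, m = geno.shape
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if snp_ids is None:
        snp_ids = [f"s{j}" for j in range(m)]
    if sample_ids is None:
        sample_ids = [f"i{j}" for j in range(n)]
    return GenotypeMatrix(geno, sample_ids, np.array(snp_ids, dtype=object),
                          np.array(chrom, dtype=object), np.array(pos, dtype=np.int64))


@pytest.fixture(scope="session")
def tiny_pop():
    """Filtered, complete tiny-preset population."""
    G = og.simulate_population(og.tiny(seed=42))
    Gf, _ = og.filter_snps(G)
    return Gf


@pytest.fixture(scope="session")
def tiny_kinship(tiny_pop):
    return og.ibs_kinship(tiny_pop)


@pytest.fixture(scope="session")
def nmri_pop():
    """Scaled-down 288-sample structured population (fewer SNPs for speed)."""
    G = og.simulate_population(og.nmri_like(seed=7, n_chroms=6))
    Gf, _ = og.filter_snps(G)
    return Gf


@pytest.fixture(scope="session")
def nmri_kinship(nmri_pop):
    return og.ibs_kinship(nmri_pop)
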