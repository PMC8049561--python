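import numpy as np
import pandas as pd
import pytest

from admixeval.demography import SimulationConfig, build_standard_tree, simulate_genotypes
from admixeval.genotype import GenotypeMatrix


def make_matrix(calls, populations, chromosome=None, genetic_pos=None):
    """Small GenotypeMatrix from a 2-D list of calls and per-individual
    population labels."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_inds = calls.shape
    if chromosome is None:
        chromosome = np.ones(n_sites, dtype=int)
    if genetic_pos is None:
        genetic_pos = np.arange(n_sites) * 1e-4
    pos = []
    counter = {}
    for c in chromosome:
        counter[c] = counter.get(c, 0) + 1
        pos.append(counter[c] * 100)
    snps = pd.DataFrame({
        "snp_id": [f"snp{i}" for i in range(n_sites)],
        "chromosome": chromosome,
        "genetic_pos": genetic_pos,
        "physical_pos": pos,
        "ref": "A",
        "alt": "G",
    })
    inds = pd.DataFrame({
        "sample_id": [f"ind{i}" for i in range(n_inds)],
        "sex": "U",
        "population": populations,
    })
    return GenotypeMatrix(snps=snps, individuals=inds, calls=calls)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_matrix(rng):
    """A 2000-site, 3-population random matrix for operator tests."""
    calls = rng.integers(0, 3, size=(2000, 15)).astype(np.int8)
    pops = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
    chrom = np.repeat([1, 2], 1000)
    gpos = np.tile(np.arange(1000) * 1e-4, 2)
    return make_matrix(calls, pops, chromosome=chrom, genetic_pos=gpos)


@pytest.fixture(scope="session")
def standard_sim():
    """One small simulated standard-tree dataset shared across tests."""
    scenario = build_standard_tree(0.5)
    config = SimulationConfig(scale=1 / 800, seed=20240917)
    return simulate_genotypes(scenario, config)
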