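import numpy as np
import pandas as pd
import pytest

from sweepscan.containers import HaplotypeMatrix, make_sites


def build_matrix(entries, positions=None, chrom="1", polarized=True, pool_id="test"):
    """HaplotypeMatrix from a plain 0/1 array (positions default to 0,1,2,...)."""
    X = np.asarray(entries, dtype=np.uint8)
    if positions is None:
        positions = np.arange(X.shape[1], dtype=np.int64)
    sites = make_sites(chrom, positions, aa=["A"] * X.shape[1])
    return HaplotypeMatrix(entries=X, sites=sites, pool_id=pool_id, polarized=polarized)


@pytest.fixture
def toy_matrix():
    """The 3-haplotype worked example: haplotypes 110, 100, 000."""
    return build_matrix([[1, 1], [1, 0], [0, 0]])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_polymorphic_matrix(rng, n_hap, n_sites):
    """Random 0/1 matrix with every column polymorphic."""
    while True:
        X = (rng.random((n_hap, n_sites)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
        cs = X.sum(axis=0)
        if np.all((cs > 0) & (cs < n_hap)):
            return X


@pytest.fixture(scope="session")
def neutral_sim():
    """One small neutral replicate shared across tests (20 haplotypes, 200 kb)."""
    from sweepscan.sweep_sim import SweepSimParams, simulate

    params = SweepSimParams(
        pop_size_haploid=60, region_bp=200_000, mu=2e-6, rho=2e-6,
        sample_haplotypes=20, seed=424242, burn_in_generations=480,
    )
    return simulate(params)
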