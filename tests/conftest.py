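import numpy as np
import pytest

from epiaco import AcoParams, GenotypeDataset, get_model, simulate_dataset


@pytest.fixture(scope="session")
def model1():
    return get_model(1)


@pytest.fixture(scope="session")
def model5():
    return get_model(5)


@pytest.fixture
def tiny_dataset():
    """Four samples, one SNP, perfectly separating genotypes."""
    return GenotypeDataset(
        genotypes=np.array([[0], [0], [2], [2]], dtype=np.int8),
        phenotype=np.array([0, 0, 1, 1], dtype=np.int8),
        snp_names=["S0"],
    )


@pytest.fixture(scope="session")
def small_model1_dataset(model1):
    """20 SNPs, 4000 samples, strong embedded pair: searchable exhaustively."""
    return simulate_dataset(model1, n_snps=20, seed=1234)


@pytest.fixture
def fast_params():
    return AcoParams(n_ants=30, n_iterations=10, seed=5)


def random_counts(rng, n_rows=9, n_max=20):
    """Random small contingency table with at least one sample."""
    while True:
        counts = rng.multinomial(
            rng.integers(1, n_max + 1), np.ones(n_rows * 2) / (n_rows * 2)
        ).reshape(n_rows, 2)
        if counts.sum() > 0:
            return counts
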