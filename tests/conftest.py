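import numpy as np
import pytest
from hypothesis import settings

from evoqtl.data import GenotypeMatrix, split_data
from evoqtl.simulate import SimConfig, simulate_additive_phenotype, simulate_hwe_genotypes

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def tiny_dataset():
    """3 samples x 2 loci with a phenotype; hand-written."""
    X = GenotypeMatrix(
        sample_ids=(0, 1, 2),
        locus_ids=("locA", "locB"),
        codes=np.array([[0, 1], [1, 2], [2, 0]]),
    )
    y = np.array([0.1, 1.2, 2.3])
    return X, y


@pytest.fixture(scope="session")
def additive_small():
    """200 samples x 8 loci, additive signal plus noise, with its split."""
    X = simulate_hwe_genotypes(SimConfig(n_samples=200, n_loci=8, maf=0.3, seed=11))
    betas = np.linspace(1.0, 0.3, 8)
    y = simulate_additive_phenotype(X, betas, noise_sd=2.0, seed=12)
    return X, y, split_data(200, 11)


@pytest.fixture(scope="session")
def noiseless_linear():
    """400 samples x 5 loci where y is exactly linear in the genotypes."""
    X = simulate_hwe_genotypes(SimConfig(n_samples=400, n_loci=5, maf=0.4, seed=3))
    y = X.codes @ np.array([2.0, -1.0, 0.5, 1.5, -0.5])
    return X, y, split_data(400, 3)
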