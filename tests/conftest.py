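import numpy as np
import pytest

from genegeo import (GenotypeMatrix, SimConfig, simulate_lattice_dataset,
                     square_grid)


@pytest.fixture(scope="session")
def structured_dataset():
    """Strong isolation-by-distance dataset on a 4x4 lattice."""
    cfg = SimConfig(grid=square_grid(4, 4, spacing=10.0), n_per_pop=10,
                    L=1000, spatial_sd=1.0, spatial_range=30.0, seed=11)
    return simulate_lattice_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """No spatial structure: all populations share allele frequencies."""
    cfg = SimConfig(grid=square_grid(3, 2, spacing=10.0), n_per_pop=5,
                    L=300, spatial_sd=0.0, seed=7)
    return simulate_lattice_dataset(cfg)


@pytest.fixture
def tiny_matrix():
    """3 individuals x 2 loci with one missing entry."""
    values = np.array([[0, 2], [1, 0], [2, 1]], dtype=np.int8)
    missing = np.zeros((3, 2), dtype=bool)
    missing[1, 1] = True
    return GenotypeMatrix(values, missing, ["a", "b", "c"],
                          ["p1", "p1", "p2"], ["l1", "l2"])


def binomial_matrix(rng, freqs_per_ind, pops, prefix="ind"):
    """Genotypes drawn row-wise from per-individual frequency vectors."""
    values = rng.binomial(2, freqs_per_ind).astype(np.int8)
    n, L = values.shape
    return GenotypeMatrix(values, np.zeros((n, L), bool),
                          [f"{prefix}{i}" for i in range(n)], list(pops),
                          [f"s{j}" for j in range(L)])
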