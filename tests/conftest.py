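import numpy as np
import pytest

import domblup as db


@pytest.fixture(scope="session")
def small_pop() -> db.TruePopulation:
    """A small complete population with SD offspring and SMGS groups."""
    cfg = db.SimConfig(
        n_animals=200,
        n_snps=120,
        n_sd_offspring=40,
        n_smgs_groups=25,
        daughters_per_group=(15, 30),
        min_group_size=20,
        seed=42,
    )
    return db.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_codings(small_pop):
    freqs = db.estimate_allele_frequencies(small_pop.genotypes)
    return db.compute_codings(small_pop.genotypes, freqs)


@pytest.fixture(scope="session")
def tiny_system():
    """n=8 fixture with dense G/D kernels for likelihood oracles."""
    rng = np.random.default_rng(123)
    n = 8
    A = rng.normal(size=(n, 5))
    G = A @ A.T / 5
    B = rng.normal(size=(n, 5))
    D = B @ B.T / 5
    y = rng.normal(size=n)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    return y, X, G, D
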