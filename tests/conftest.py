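import numpy as np
import pytest

from magne.simulate import SimulationConfig, simulate_population

STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]


@pytest.fixture(scope="session")
def small_population():
    """A small simulated panmictic population reused across tests."""
    cfg = SimulationConfig(
        n_genomes=4, n_families=20, codons_per_family=60, theta4=0.02, seed=42
    )
    genomes, truth = simulate_population(cfg)
    return cfg, genomes, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


def random_cds(rng, n_codons):
    idx = rng.integers(0, len(SENSE_CODONS), n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)
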