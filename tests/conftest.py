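import io

import numpy as np
import pytest

from snppop.dataset import make_dataset
from snppop.io import read_ped_map
from snppop.simulate import SimulationConfig, simulate_balding_nichols


def dataset_from_text(ped_text: str, map_text: str, autosomes="numeric"):
    """Build a dataset from inline PED/MAP strings."""
    return read_ped_map(io.StringIO(ped_text), io.StringIO(map_text), autosomes=autosomes)


@pytest.fixture(scope="session")
def bn_two_pop():
    """Two Balding-Nichols demes at target F_ST 0.15 (n=50/pop, 5000 variants)."""
    cfg = SimulationConfig(
        n_populations=2, n_samples_per_pop=50, n_variants_per_chrom=5000, target_fst=0.15, seed=101
    )
    return simulate_balding_nichols(cfg)


@pytest.fixture(scope="session")
def bn_three_pop_small():
    """Three moderately differentiated demes for structure/network tests."""
    cfg = SimulationConfig(
        n_populations=3,
        n_samples_per_pop=12,
        n_chromosomes=2,
        n_variants_per_chrom=400,
        target_fst=0.15,
        missing_rate=0.01,
        seed=102,
    )
    return simulate_balding_nichols(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_dataset(rng, n=20, m=50, missing_rate=0.1, n_pops=1):
    """Unstructured random genotypes with missingness (no LD, no structure)."""
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate:
        calls[rng.random((n, m)) < missing_rate] = -1
    pops = [f"P{i % n_pops + 1}" for i in range(n)]
    return make_dataset(calls, populations=pops)
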