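import numpy as np
import pandas as pd
import pytest

from recurve.pedigree import sort_pedigree
from recurve.simulate import SimConfig, simulate_pedigree, simulate_ra_dataset, simulate_rep_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_random_pedigree(n_animals: int, seed: int = 0):
    """Random multi-generation pedigree used by the matrix oracles."""
    cfg = SimConfig(seed=seed, n_founders=max(10, n_animals // 8),
                    n_generations=4,
                    cows_per_generation=max(1, (n_animals - n_animals // 8) // 4),
                    n_sires_per_generation=4)
    return simulate_pedigree(cfg)


@pytest.fixture(scope="session")
def trio_frame():
    return pd.DataFrame({
        "animal": ["sire", "dam", "kid"],
        "sire": ["0", "0", "sire"],
        "dam": ["0", "0", "dam"],
        "birth_year": [2000, 2000, 2002],
        "sex": ["M", "F", "F"],
    })


@pytest.fixture(scope="session")
def fullsib_ped():
    """Two unrelated founder pairs -> full sibs s1, s2 -> inbred offspring."""
    frame = pd.DataFrame({
        "animal": ["f1", "f2", "s1", "s2", "kid"],
        "sire": ["0", "0", "f1", "f1", "s1"],
        "dam": ["0", "0", "f2", "f2", "s2"],
    })
    return sort_pedigree(frame)


@pytest.fixture(scope="session")
def small_rep_dataset():
    cfg = SimConfig(seed=42, n_founders=50, n_generations=3, cows_per_generation=90)
    return simulate_rep_dataset(cfg)


@pytest.fixture(scope="session")
def small_ra_dataset():
    cfg = SimConfig(seed=43, n_founders=50, n_generations=3, cows_per_generation=90)
    return simulate_ra_dataset(cfg)
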