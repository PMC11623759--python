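import numpy as np
import pandas as pd
import pytest

from mica.cohort import PlantedClique, SimulationConfig, generate_cohort
from mica.prep import FeatureTable


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the generator's default settings (two planted cliques,
    n=360, 18.9% food insecure)."""
    return generate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort for plumbing tests."""
    cfg = SimulationConfig(
        n_samples=80,
        n_taxa=12,
        planted_cliques=[PlantedClique(taxa=(0, 1), effect_secure=0.1, effect_insecure=0.3)],
        missing_rate=0.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def tiny_table():
    """Hand-sized feature table with one absent-in-most taxon."""
    data = pd.DataFrame(
        {
            "T0": [0.5, 0.4, 0.6, 0.2],
            "T1": [0.5, 0.6, 0.0, 0.8],
            "T2": [0.0, 0.0, 0.4, 0.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return FeatureTable(data)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
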