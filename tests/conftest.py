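"""Shared fixtures: one synthetic chronosequence reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from traitassembly.data import REGENERATIVE_SCHEMA, TraitTable
from traitassembly.simulate import AssemblyConfig, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default-condition synthetic dataset (fixed seed, generated once)."""
    return simulate_dataset(AssemblyConfig(seed=7))


@pytest.fixture(scope="session")
def community(dataset):
    return dataset.community


@pytest.fixture()
def small_traits():
    """Five species x five regenerative traits, fully observed."""
    df = pd.DataFrame(
        {
            "seed_mass": [0.5, 2.0, 8.0, 1.0, 4.0],
            "longevity": [1, 2, 3, 4, 2],
            "flowering_period": [3, 6, 9, 12, 5],
            "fruiting_period": [2, 4, 8, 11, 6],
            "fmf": [0, 4, 7, 13, 5],
        },
        index=[f"sp{i}" for i in range(1, 6)],
    )
    df.index.name = "species"
    return TraitTable(df, dict(REGENERATIVE_SCHEMA))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
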