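import numpy as np
import pandas as pd
import pytest

from stromalab import synthetic as syn
from stromalab.diversity import OTUTable


@pytest.fixture(scope="session")
def fresh_solution():
    """Noise-free steady-state profile and truth for the 'fresh' preset."""
    return syn.solve_steady_profile(syn.PRESETS["fresh"])


@pytest.fixture(scope="session")
def modified_solution():
    return syn.solve_steady_profile(syn.PRESETS["modified"])


@pytest.fixture(scope="session")
def dark_solution():
    return syn.solve_steady_profile(syn.PRESETS["dark"])


@pytest.fixture()
def small_table():
    """Hand-sized OTU table with phylum labels for oracle comparisons."""
    counts = pd.DataFrame(
        {
            "A": [10, 5, 0, 1, 2, 30],
            "B": [0, 8, 4, 0, 2, 20],
            "C": [1, 1, 1, 1, 1, 1],
        },
        index=[f"otu{i}" for i in range(6)],
    )
    phylum = pd.Series(
        ["P1", "P1", "P2", "P2", "P3", "P3"], index=counts.index
    )
    return OTUTable(counts, phylum=phylum, similarity=0.97)
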