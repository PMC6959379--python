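import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from meshbag.community import OtuTable

# Deterministic hypothesis runs: no example database, fixed derivation.
settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    """Small OTU x column count matrix exercising the filter rules.

    A: abundant everywhere; B: 9 reads in one column; C: 9 reads spread
    over three columns; D: 10 reads in one column.
    """
    return pd.DataFrame(
        {
            "S1_r1": [100, 9, 3, 10],
            "S1_r2": [120, 0, 3, 0],
            "S2_r1": [80, 0, 3, 0],
            "S2_r2": [90, 0, 0, 0],
        },
        index=["A", "B", "C", "D"],
    )


@pytest.fixture
def toy_table(toy_counts) -> OtuTable:
    groups = {c: c.split("_")[0] for c in toy_counts.columns}
    guild = {"A": "ECM", "B": "saprotroph", "C": "saprotroph", "D": "pathogen"}
    return OtuTable(counts=toy_counts, replicate_groups=groups, guild=guild)


@pytest.fixture(scope="session")
def otu_experiment():
    """One seeded synthetic OTU experiment shared across tests."""
    from meshbag.synthetic import OtuScenario, gen_otu_experiment

    return gen_otu_experiment(OtuScenario(seed=7))


def gaussian(x, area, center, fwhm):
    """Reference Gaussian used by oracle computations in tests."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -((x - center) ** 2) / (2 * sigma**2))
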