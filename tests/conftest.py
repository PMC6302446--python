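import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from comboscreen import SimConfig, simulate_dataset
from comboscreen.simulate import generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_screen():
    """One default synthetic screen shared across the session."""
    return generate(SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_dataset():
    """Model-ready dataset + screen from the default configuration."""
    return simulate_dataset(SimConfig(seed=0))


@pytest.fixture
def tiny_response():
    """One cell line, two drugs, singles plus a pair."""
    return pd.DataFrame(
        {
            "CELL": ["C1", "C1", "C1"],
            "DRUG_A": ["A", "B", "A"],
            "DRUG_B": [pd.NA, pd.NA, "B"],
            "MIN_GROWTH": [0.5, 0.6, 0.2],
        }
    ).astype({"DRUG_B": "string"})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
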