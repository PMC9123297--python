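import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

from mipool.ampute import MissingnessSpec, ampute
from mipool.friedman import FriedmanConfig, simulate_normal


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-row normal-outcome Friedman dataset."""
    return simulate_normal(FriedmanConfig(n_rows=300, seed=101))


@pytest.fixture(scope="session")
def small_amputed(small_dataset):
    """The small dataset with default MAR missingness at 35%."""
    return ampute(small_dataset, MissingnessSpec(mechanism="MAR", seed=202))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(777)
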