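import numpy as np
import pandas as pd
import pytest

from gutcross import synthetic as syn


@pytest.fixture(scope="session")
def small_config() -> syn.GeneratorConfig:
    """Desk-scale study conditions: full crossover layout, reduced depth."""
    return syn.GeneratorConfig(seed=11, scale=0.05)


@pytest.fixture(scope="session")
def small_design(small_config) -> pd.DataFrame:
    return syn.generate_design(small_config)


@pytest.fixture(scope="session")
def small_counts(small_design, small_config):
    counts, ledger = syn.generate_counts(small_design, small_config)
    return counts, ledger


@pytest.fixture(scope="session")
def null_counts(small_design):
    cfg = syn.GeneratorConfig(seed=11, scale=0.05, bacteroides_fold=1.0)
    counts, ledger = syn.generate_counts(small_design, cfg)
    return counts, ledger


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
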