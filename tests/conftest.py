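import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import protnet as pn


@pytest.fixture(scope="session")
def small_community():
    """A compact strongly-structured community shared by read-only tests."""
    cfg = pn.SyntheticConfig(
        n_asvs=20, n_months=60, missing_month_fraction=0.1,
        n_planted_edges=8, library_size=20_000, seed=11,
    )
    table, taxonomy, truth = pn.generate_community(cfg)
    return cfg, table, taxonomy, truth


@pytest.fixture()
def monthly_dates():
    def make(n, start="2003-09-01"):
        dates = pd.date_range(start, periods=n, freq="MS")
        idx = [f"s{i}" for i in range(n)]
        return pd.Series(dates, index=idx)
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
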