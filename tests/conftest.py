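import numpy as np
import pandas as pd
import pytest

from stagesen.synthetic_data import published_tables


@pytest.fixture(scope="session")
def tables() -> dict[str, pd.DataFrame]:
    """Packaged transcriptions of the published per-cancer tables."""
    return published_tables()


@pytest.fixture(scope="session")
def fit_table(tables) -> pd.DataFrame:
    """All three parameter tables stacked, as a fit-result-style table."""
    return pd.concat([tables["male"], tables["female"], tables["pooled"]],
                     ignore_index=True)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
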