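import numpy as np
import pandas as pd
import pytest

from spreadday.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact but complete synthetic dataset shared across tests."""
    cfg = SyntheticConfig(seed=11, n_years=6, n_fires_per_year=6,
                          true_threshold={"ffmc": 88.0})
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def paired_rows(small_dataset):
    """The canonical paired daily-growth / fire-weather analysis table."""
    return small_dataset.growth


def make_paired(values, areas, years=None, variable="ffmc"):
    """Minimal paired table from raw index values and burned areas."""
    n = len(values)
    df = pd.DataFrame({
        variable: np.asarray(values, dtype=float),
        "area": np.asarray(areas, dtype=float),
        "year": years if years is not None else np.full(n, 2001),
    })
    return df
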