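import warnings

import numpy as np
import pandas as pd
import pytest

from soilkrige import SyntheticConfig, simulate_fields

warnings.filterwarnings("ignore", message="duplicate sample locations")


@pytest.fixture(scope="session")
def default_survey() -> pd.DataFrame:
    """One default synthetic survey (351 sites), reused across tests."""
    return simulate_fields(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def survey_batch() -> list[pd.DataFrame]:
    """30 replicate surveys at n=1000 for distribution-level checks."""
    tables = []
    for seed in range(30):
        cfg = SyntheticConfig(n_sites=1000, n_calibration=97, seed=seed)
        tables.append(simulate_fields(cfg))
    return tables


def line_samples(values, **extra) -> pd.DataFrame:
    """Samples on the x-axis at integer coordinates."""
    values = np.asarray(values, dtype=float)
    base = {"id": np.arange(len(values)), "x": np.arange(len(values), dtype=float),
            "y": np.zeros(len(values))}
    base.update(extra)
    base["v"] = values
    return pd.DataFrame(base)
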