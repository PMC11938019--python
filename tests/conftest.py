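import numpy as np
import pandas as pd
import pytest

import dendro_isophys as di


@pytest.fixture(scope="session")
def env_default():
    """One synthetic driver table shared across tests (seed fixed)."""
    return di.synth_environment(di.EnvParams(), seed=42)


@pytest.fixture(scope="session")
def paper_scenario():
    """One paper-like scenario shared across tests."""
    return di.make_scenario("paper_like", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_iso():
    """Two isotope rows: one annual cellulose, one 5-year wood segment."""
    return pd.DataFrame({
        "tree_id": ["T1", "T2"],
        "species": ["spruce", "spruce"],
        "year_start": [1990, 1816],
        "year_end": [1990, 1820],
        "material": ["cellulose", "wood"],
        "d13c": [-22.0, -24.0],
        "d15n": [np.nan, -4.0],
        "d18o": [30.0, np.nan],
    })
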