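import numpy as np
import pandas as pd
import pytest

from gonad.config import SyntheticConfig
from gonad.synthetic import generate_cell_table, ground_truth_profiles


@pytest.fixture(scope="session")
def default_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Coarse imaging geometry to keep synthetic frames small."""
    return SyntheticConfig(
        seed=7,
        gonad_length=80.0,
        gonad_radius=8.0,
        rachis_radius=4.0,
        pixel_size=0.25,
        frame_interval=2.0,
    )


@pytest.fixture(scope="session")
def default_cells(default_cfg) -> pd.DataFrame:
    return generate_cell_table(default_cfg)


@pytest.fixture(scope="session")
def default_truth(default_cfg) -> pd.DataFrame:
    return ground_truth_profiles(default_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
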