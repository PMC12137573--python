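import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

sys.path.insert(0, str(Path(__file__).parent))

hyp_settings.register_profile("suite", deadline=None, derandomize=True)
hyp_settings.load_profile("suite")

from listendiv.config import LogLinear, SimulationConfig
from listendiv import synthetic as sy

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def tiny_config():
    """A fast generator configuration shared across unit tests."""
    return SimulationConfig(
        seed=42,
        n_areas=8,
        area_size_range=(120, 600),
        n_songs=600,
        n_genres=8,
        embed_dim=16,
        stream_count_mean=140.0,
        breadth_size_slope=0.06,
        taste_concentration_by_size=LogLinear(1.8, 2.0),
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    """Catalog, population and streams for the tiny configuration."""
    catalog = sy.generate_catalog(tiny_config)
    population = sy.generate_population(tiny_config)
    streams = sy.generate_streams(population, catalog, tiny_config)
    return catalog, population, streams


@pytest.fixture()
def toy_streams():
    """Hand-built 10-event stream table exercising the duration filter."""
    return pd.DataFrame(
        {
            "user_id": ["u1"] * 5 + ["u2"] * 5,
            "song_id": [f"s{i}" for i in range(10)],
            "location_id": ["L1"] * 10,
            "duration_s": [29.0, 31.0, 45.0, 10.0, 200.0, 30.0, 29.9, 60.0, 90.0, 120.0],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
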