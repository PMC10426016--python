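import numpy as np
import pandas as pd
import pytest

import revoquant as rq


@pytest.fixture(scope="session")
def small_config():
    return rq.GeneratorConfig(n_individuals=400, n_countries=4,
                              time_start=1300, time_end=1600, seed=42)


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, latents = rq.simulate_panel(small_config)
    return panel


@pytest.fixture()
def tiny_bios():
    """Three scored individuals from the worked national-product example."""
    return pd.DataFrame(
        {
            "id": [0, 1, 2],
            "country": ["france", "france", "france"],
            "birth_year": [1600, 1610, 1650],
            "death_year": [1660, 1680, 1710],
            "score": [1.0, 2.0, 4.0],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
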