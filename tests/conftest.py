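import numpy as np
import pytest

from infuselog import (
    CareAreaMap,
    DrugMap,
    HalfLifeTable,
    load_fixture_tables,
    nicu_default_config,
    simulate_event_log,
)


@pytest.fixture(scope="session")
def fixture_tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def default_maps():
    return CareAreaMap.default(), DrugMap.default(), HalfLifeTable.default()


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated log (seed 7, 50 infusions) with its ground truth."""
    config = nicu_default_config(n_infusions=50, seed=7)
    events, truth = simulate_event_log(config)
    return config, events, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
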