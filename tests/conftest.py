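import logging

import pytest

from herdecon.config_io import (
    bundled_config_path,
    load_breed_config,
    load_price_table,
)

logging.getLogger("herdecon").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def lbw():
    return load_breed_config(bundled_config_path("lbw"))


@pytest.fixture(scope="session")
def lr():
    return load_breed_config(bundled_config_path("lr"))


@pytest.fixture(scope="session")
def lrog():
    return load_breed_config(bundled_config_path("lrog"))


@pytest.fixture(scope="session")
def prices_lbw():
    return load_price_table(bundled_config_path("prices_lbw"))


@pytest.fixture(scope="session")
def prices_lr():
    return load_price_table(bundled_config_path("prices_lr"))


@pytest.fixture(scope="session")
def prices_lrog():
    return load_price_table(bundled_config_path("prices_lrog"))


@pytest.fixture(scope="session")
def lbw_small_run(lbw):
    """One small shared simulation for cheap assertions."""
    from herdecon.simulator import simulate_batch

    return simulate_batch(lbw, years=8, burn_in=3, seed=42, n_replicates=20)
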