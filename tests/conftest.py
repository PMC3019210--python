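import numpy as np
import pandas as pd
import pytest

from coxmiss.amputation import DEFAULT_PATTERN_TABLE, AmputationConfig, impose_mar
from coxmiss.population import default_config, draw_bootstrap_sample, generate_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def population():
    """Default-config population, reused read-only across tests."""
    return generate_population(default_config(seed=42))


@pytest.fixture(scope="session")
def sample1000(population):
    rng = np.random.default_rng(7)
    return draw_bootstrap_sample(population, 1000, rng)


@pytest.fixture(scope="session")
def incomplete50(sample1000):
    rng = np.random.default_rng(11)
    return impose_mar(sample1000, DEFAULT_PATTERN_TABLE, AmputationConfig(p0=0.5), rng)


@pytest.fixture
def toy_survival():
    """Tiny deterministic survival frame for hand-checkable oracles."""
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 0, 1],
        }
    )
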