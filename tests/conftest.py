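import pandas as pd
import pytest

from snakeburden.config import SimulationConfig, standard_population_weights
from snakeburden import synthetic


@pytest.fixture(scope="session")
def standard():
    return pd.Series(standard_population_weights())


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic survey with spatial signal, dual-coder noise and
    interleaved other-cause deaths, shared across tests."""
    cfg = SimulationConfig(
        n_units=250,
        seed=42,
        years=tuple(range(2004, 2014)),
        base_rate=30.0,
        spatial_sd=0.5,
        spatial_range=3.0,
        other_cause_ratio=5.0,
        mean_unit_population=5000,
        confusion_rate=0.002,
    )
    return synthetic.simulate(cfg)
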