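import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mcflfer as m

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def descriptors() -> pd.DataFrame:
    return m.load_solute_table()


@pytest.fixture(scope="session")
def full_obs() -> m.ObservationSet:
    """Complete balanced design: 37 solutes x 90 cells x 3 replicates."""
    obs, _ = m.generate(m.default_config(seed=11, dropout=0.0))
    return obs


@pytest.fixture(scope="session")
def default_obs() -> m.ObservationSet:
    """One draw at the study defaults (dropout 0.535, noise 0.25)."""
    obs, _ = m.generate(m.default_config(seed=7))
    return obs
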