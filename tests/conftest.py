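import pytest
from hypothesis import settings

from cochlear_cea import (Arm, default_life_table, default_parameters,
                          strategy_for)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    """Packaged parameter set mirroring the published tables."""
    return default_parameters()


@pytest.fixture(scope="session")
def lt():
    """Packaged synthetic high-longevity life table (e0 ~ 83 y)."""
    return default_life_table()


@pytest.fixture(scope="session")
def strategies():
    return {arm: strategy_for(arm) for arm in Arm}
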