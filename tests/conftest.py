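import dataclasses

import numpy as np
import pytest

from pondipm import ParameterDraw, PondScenario, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def draw():
    """The shipped synthetic mean coefficient set."""
    return ParameterDraw()


@pytest.fixture
def det_draw():
    """Deterministic-kernel coefficient set (zero residual spreads)."""
    return dataclasses.replace(ParameterDraw(), growth_sd=0.0, meta_sd=0.0)


@pytest.fixture
def zero_spread_config():
    """Synthesis config whose draws all equal the means."""
    return SyntheticConfig(n_draws=3, spreads={k: 0.0 for k in _all_spread_keys()})


def _all_spread_keys():
    from pondipm.params import DEFAULT_SPREADS

    return DEFAULT_SPREADS.keys()


@pytest.fixture
def native_scenario():
    return PondScenario(hydroperiod_days=110.0, prop_hybrid=0.0)


@pytest.fixture
def mixed_scenario():
    return PondScenario(hydroperiod_days=110.0, prop_hybrid=0.5)
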