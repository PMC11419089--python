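"""Shared fixtures: cached speed sweeps of the calibrated model.

The behavioural tests compare intact and hemisected sweeps across several
protocols; simulations are cached per session so each (condition,
protocol) pair is integrated once.
"""

import pytest

from hemigait.config import ModelConfig
from hemigait.engine import run_sweep


@pytest.fixture(scope="session")
def model_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def sweep_cache(model_config):
    cache = {}

    def get(condition: str, protocol: str, grid_step: float = 0.1):
        key = (condition, protocol, grid_step)
        if key not in cache:
            cache[key] = run_sweep(condition, protocol, model_config,
                                   grid_step=grid_step)
        return cache[key]

    return get
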