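from dataclasses import replace

import pytest

from dentdist.simulate import SimGrid, default_config, run_cached


@pytest.fixture(scope="session")
def fast_config():
    """Default physics on a shortened horizon, for structural tests."""
    cfg = default_config()
    return replace(cfg, grid=replace(cfg.grid, n_years=10, burn_in_years=4))


@pytest.fixture(scope="session")
def fast_result(fast_config):
    """One cached simulation of the fast configuration."""
    return run_cached(fast_config)


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()
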