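import pytest
from hypothesis import HealthCheck, settings

import braindose as bd

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return bd.EnergyGrid.default()


@pytest.fixture(scope="session")
def head():
    return bd.HeadModel()


@pytest.fixture(scope="session")
def ensemble(grid):
    """53-event power-law SEP ensemble, gamma in [2, 4], fixed seed."""
    return bd.make_sep_ensemble(bd.EnsembleSpec(seed=7, n_events=53), grid)
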