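import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import endosim as es

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def params() -> es.Params:
    return es.Params()


@pytest.fixture()
def small_params() -> es.Params:
    """A single-macrophage world for fast unit tests."""
    p = es.Params()
    p.engine.n_macrophages = 1
    return p


@pytest.fixture()
def cell_world(small_params) -> es.World:
    return es.World(small_params, seed=7)


@pytest.fixture()
def empty_world(params) -> es.World:
    return es.World(params, seed=7, n_macrophages=0)


def free_tnf(world: es.World) -> int:
    return int(np.count_nonzero(world.tnf["bound"] == 0)) if world.tnf.n else 0
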