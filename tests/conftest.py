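import numpy as np
import pytest

import petkin as pk


@pytest.fixture(scope="session")
def schedule():
    return pk.default_schedule()


@pytest.fixture(scope="session")
def config():
    return pk.GeneratorConfig()


@pytest.fixture(scope="session")
def input_fn(config):
    fn, _ = pk.synth_input_function(config)
    return fn


@pytest.fixture(scope="session")
def blood_tac(config):
    _, blood = pk.synth_input_function(config)
    return blood


@pytest.fixture(scope="session")
def fine_constant_input():
    """Unit plasma concentration sampled on 3-s frames over 60 min, so the
    piecewise-linear interpolation is indistinguishable from Cp = 1."""
    n = 1200
    ends = np.arange(1, n + 1) * 3.0
    sched = pk.FrameSchedule(starts=ends - 3.0, ends=ends)
    return pk.InputFunction(schedule=sched, values=np.ones(n))
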