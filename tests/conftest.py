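import numpy as np
import pytest

from cbmsim.arm import ArmParams, ArmState, reset_arm
from cbmsim.loop import LoopConfig, derive_task_ranges
from cbmsim.metrics import MetricConfig
from cbmsim.network import MicrocomplexConfig
from cbmsim.protocol import DEFAULT_CENTRE, ProtocolConfig, desk_scale_protocol


@pytest.fixture(scope="session")
def arm_params():
    return ArmParams()


@pytest.fixture(scope="session")
def metric_config():
    return MetricConfig()


@pytest.fixture(scope="session")
def small_net_config():
    """A small microcomplex for fast unit tests (1000 GCs)."""
    return MicrocomplexConfig(n_mf=10)


@pytest.fixture(scope="session")
def desk_protocol():
    return desk_scale_protocol()


@pytest.fixture(scope="session")
def task_ranges(arm_params, desk_protocol):
    return derive_task_ranges(arm_params, DEFAULT_CENTRE,
                              desk_protocol.target_radius)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
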