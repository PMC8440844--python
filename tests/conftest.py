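import numpy as np
import pytest

from voxphys.params import default_params
from voxphys.posture import MuscleActivation, posture_from_activations
from voxphys.synth import SimulationControls, simulate
from voxphys.tbcm import rules_update


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def rest_posture(params):
    return posture_from_activations(MuscleActivation.rest(), params)


@pytest.fixture(scope="session")
def mid_posture(params):
    act = MuscleActivation(a_LCA=0.5, a_IA=0.5, a_PCA=0.0, a_CT=0.5, a_TA=0.5)
    return posture_from_activations(act, params)


@pytest.fixture(scope="session")
def mid_config(params, mid_posture):
    return rules_update(mid_posture, params, a_TA=0.5)


@pytest.fixture(scope="session")
def mid_sim(params):
    """One phonating mid-grid simulation, shared across tests."""
    ctl = SimulationControls(pl=1100.0, act=MuscleActivation(0.5, 0.5, 0.0, 0.5, 0.5))
    res = simulate(ctl, params)
    assert not res.failed
    return res


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
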