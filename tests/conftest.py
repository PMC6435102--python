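import numpy as np
import pytest

from hpbrain import AcquisitionProtocol
from hpbrain.protocol import default_basis
from hpbrain.synth import AifParams, KineticParams, simulate_dynamics


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def basis():
    return default_basis()


@pytest.fixture(scope="session")
def whole_brain_params():
    """Representative whole-brain exchange parameters used across tests."""
    return KineticParams(k_pl=0.012, k_pb=0.002,
                         rho_p=1 / 26, rho_l=1 / 26, rho_b=1 / 26)


@pytest.fixture(scope="session")
def whole_brain_dynamics(protocol, whole_brain_params):
    return simulate_dynamics(whole_brain_params, protocol, AifParams())
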