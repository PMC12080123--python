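import numpy as np
import pytest

from elqdo.model import ElQdoSystem, Nucleus, QdoSpec, make_qdo
from elqdo.wavefunction import AnsatzParameters, hydrogen_1s_orbitals

AR_OMEGA = 0.7272
AR_EXACT_ENERGY = 1.5 * AR_OMEGA  # 1.0908


@pytest.fixture
def ar_qdo_system():
    """A single argon-parameter Drude oscillator at the origin."""
    return ElQdoSystem(qdos=[make_qdo("Ar", [0.0, 0.0, 0.0])])


@pytest.fixture
def ar_exact_params(ar_qdo_system):
    """Exact Gaussian ground state of the isolated oscillator."""
    return AnsatzParameters.qdo_ground_state(ar_qdo_system)


@pytest.fixture
def hydrogen_system():
    return ElQdoSystem(nuclei=[Nucleus([0.0, 0.0, 0.0], 1)], n_up=1)


@pytest.fixture
def hydrogen_exact_params():
    return AnsatzParameters(mo=hydrogen_1s_orbitals([0.0, 0.0, 0.0], zeta=1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
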