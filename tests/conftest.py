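import numpy as np
import pytest

from gelforge.energy import LJCoulombModel
from gelforge.structures import Molecule
from gelforge.synthetic import ToyHostSpec, make_rod_guest, make_toy_host


@pytest.fixture(scope="session")
def lj_model():
    return LJCoulombModel()


@pytest.fixture(scope="session")
def toy_host():
    """Ring host with a 5 Å cavity plus its exact cavity frame."""
    return make_toy_host(ToyHostSpec())


@pytest.fixture(scope="session")
def rod_guest():
    """5-site rod guest with end markers."""
    return make_rod_guest(4.0, 5)


@pytest.fixture
def lj_site_pair():
    """Two uncharged generic LJ sites (sigma 3.4, epsilon 0.1)."""
    def make(r):
        m1 = Molecule(["X"], [[0.0, 0.0, 0.0]])
        m2 = Molecule(["X"], [[r, 0.0, 0.0]])
        return m1, m2
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
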