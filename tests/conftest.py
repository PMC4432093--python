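import numpy as np
import pytest

from pureshift import Simulator, minimal_pair
from pureshift.shapes import characterize, reburp_shape
from pureshift.spin_core import Spin, SpinSystem


@pytest.fixture(scope="session")
def hn_pair():
    """Bare HN pair (no passive proton), J_NH = 90 Hz."""
    spins = [Spin("HN", "H1", 8.24, T2=0.060, role="active"),
             Spin("N", "N15", 117.0, T2=0.15)]
    J = np.zeros((2, 2))
    J[0, 1] = J[1, 0] = 90.0
    return SpinSystem(spins, J)


@pytest.fixture(scope="session")
def amide_triplet():
    """HN-N-HA fragment with 3J_HH = 8 Hz, T2 = 60 ms."""
    return minimal_pair(J_hh=8.0, T2=0.060)


@pytest.fixture(scope="session")
def amide_triplet_nj():
    """Same fragment without the homonuclear coupling (contract fixture)."""
    return minimal_pair(J_hh=0.0, T2=0.060)


@pytest.fixture()
def sim_norelax(amide_triplet_nj):
    return Simulator(amide_triplet_nj, relaxation=False)


@pytest.fixture(scope="session")
def reburp_2p22():
    """Calibrated reBURP characterisation at 2.22 ms (cached per session)."""
    return characterize(reburp_shape(256), 2.22e-3)
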