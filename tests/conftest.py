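import numpy as np
import pytest

from backpaint.geometry import rotation_about_axis
from backpaint.model import IdealGeometry
from backpaint.synthetic import make_chain


def wrap_diff(a, b):
    """Absolute angular difference in degrees, shortest way around."""
    return np.abs(((np.asarray(a) - np.asarray(b) + 180.0) % 360.0) - 180.0)


def random_rotation(rng):
    axis = rng.normal(size=3)
    return rotation_about_axis(axis, rng.uniform(0, 360))


def ca_forward_rodrigues(state, phi, psi):
    """Independent forward kinematics for the controlled CA: rotate the
    current atoms about the two torsion axes with Rodrigues matrices
    (no internal-coordinate placement involved)."""
    ci = state.controlled_index
    prev = state.chain[ci - 1]
    cur = state.chain[ci]
    phi0, psi0 = state.torsions[ci - 1]
    n_p, ca_p, c_p = prev["N"], prev["CA"], prev["C"]
    ca_i = cur["CA"]
    # phi: rotate everything past CA_prev about the N_prev->CA_prev line
    R1 = rotation_about_axis(ca_p - n_p, phi - phi0)
    rot1 = lambda p: ca_p + R1 @ (p - ca_p)
    c_p1, ca_i1 = rot1(c_p), rot1(ca_i)
    # psi: rotate everything past C_prev about the CA_prev->C_prev line
    R2 = rotation_about_axis(c_p1 - ca_p, psi - psi0)
    return c_p1 + R2 @ (ca_i1 - c_p1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def geom():
    return IdealGeometry()


@pytest.fixture
def helix_chain():
    return make_chain(12, "alpha")


@pytest.fixture
def coil_chain():
    return make_chain(30, "random", seed=5)
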