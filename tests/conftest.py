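import numpy as np
import pytest

from modexcite.dynamics import ForceFieldParams
from modexcite.modes import ENMConfig, build_enm_hessian, diagonalize, select_modes
from modexcite.structure import Structure, select
from modexcite.synthetic import SyntheticSpec, make_two_domain_system


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def system(default_spec):
    """(Structure, ForceFieldParams) of the default 52-bead two-domain system."""
    return make_two_domain_system(default_spec)


@pytest.fixture(scope="session")
def structure(system):
    return system[0]


@pytest.fixture(scope="session")
def params(system):
    return system[1]


@pytest.fixture(scope="session")
def tail_selection(structure, default_spec):
    lo = default_spec.n_core + 1
    hi = default_spec.n_atoms
    return select(structure, f"resid {lo}:{hi}")


@pytest.fixture(scope="session")
def modeset(structure):
    h = build_enm_hessian(structure, ENMConfig())
    return diagonalize(h, structure.masses)


@pytest.fixture(scope="session")
def selected_modes(modeset, tail_selection):
    return select_modes(modeset, tail_selection, 4)


def make_diatomic(k=10.0, r0=2.0, mass=110.0):
    """Two beads on the x-axis joined by one harmonic bond at equilibrium."""
    s = Structure.from_beads(
        np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]), masses=mass
    )
    p = ForceFieldParams(
        bonds=np.array([[0, 1]]),
        bond_k=np.array([k]),
        bond_r0=np.array([r0]),
        angles=np.empty((0, 3), dtype=int),
        angle_k=np.empty(0),
        angle_theta0=np.empty(0),
        charges=np.zeros(2),
        lj_eps=np.zeros(2),
        lj_rmin_half=np.full(2, 2.0),
    )
    return s, p


@pytest.fixture
def diatomic():
    return make_diatomic()
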