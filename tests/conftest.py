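import numpy as np
import pytest

from biofilmdem import AgentState, Domain, Parameters, mass_from_radius
from biofilmdem.agents import HET


@pytest.fixture(scope="session")
def domain():
    """Small ribbon domain used throughout the unit tests."""
    return Domain(L_x=40.0, L_y=10.0, L_z=40.0, N_x=12, N_y=4, N_z=12)


@pytest.fixture(scope="session")
def params(domain):
    """Soft-spring parameter set (desk-scale mechanics) resolved on the
    small domain."""
    return Parameters(k_n=1e-6).resolved(domain)


@pytest.fixture(scope="session")
def p(params):
    return params.internal()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def single_cell(p, position, radius=0.5, group=HET):
    a = AgentState.empty()
    a.append(np.array([group], np.int8), np.asarray(position, float),
             mass_from_radius(radius, p.rho_X))
    return a


@pytest.fixture()
def two_overlapping(p):
    """Two equal spheres overlapping by 10% of the diameter sum."""
    a = AgentState.empty()
    m = mass_from_radius(0.5, p.rho_X)
    a.append(np.full(2, HET, np.int8),
             np.array([[20.0, 5.0, 5.0], [20.9, 5.0, 5.0]]), m)
    return a
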