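import numpy as np
import pytest

from mdcell.mesh import RestState, TriMesh, deflate_to_biconcave, icosphere

R_CELL = 3.25e-6


@pytest.fixture(scope="session")
def sphere_162():
    return icosphere(2, R_CELL)


@pytest.fixture(scope="session")
def sphere_642():
    return icosphere(3, R_CELL)


@pytest.fixture(scope="session")
def biconcave_162():
    """162-node biconcave RBC mesh (deterministic deflation)."""
    return deflate_to_biconcave(icosphere(2, R_CELL), 0.6)


@pytest.fixture()
def rng():
    return np.random.default_rng(20130917)


@pytest.fixture(scope="session")
def perturbed_tetra():
    """Small closed mesh with non-trivial dihedral angles for gradient checks."""
    nodes = np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.1, -0.05],
        [0.4, 1.1, 0.08],
        [0.55, 0.4, 0.9],
    ])
    tris = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
    m = TriMesh(nodes, tris)
    m.validate()
    return m
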