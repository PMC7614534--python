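import numpy as np
import pytest

from tissuesim.cells import Cell, CellPopulation
from tissuesim.geometry import build_honeycomb_mesh


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def mesh_with_cells(nx, ny, edge=1.0, types=None, rng=None):
    """Honeycomb mesh plus one cell per element (target area = actual area)."""
    mesh = build_honeycomb_mesh(nx, ny, edge)
    n = len(mesh.elements)
    if types is None:
        types = [0] * n
    elif types == "random":
        types = [int(rng.random() < 0.5) for _ in range(n)]
    cells = CellPopulation(
        [
            Cell(id=eid, type_label=types[eid], target_area=mesh.element_area(eid))
            for eid in sorted(mesh.elements)
        ]
    )
    return mesh, cells


def perturb(mesh, rng, scale=0.05):
    for node in mesh.nodes.values():
        node.position = node.position + scale * rng.standard_normal(2)
    return mesh


@pytest.fixture
def honeycomb_3x3(rng):
    return mesh_with_cells(3, 3, rng=rng)


@pytest.fixture
def two_type_mesh(rng):
    return mesh_with_cells(3, 3, types="random", rng=rng)


def numerical_gradient(energy_fn, get, set_, h=1e-6):
    """Central-difference gradient of energy_fn w.r.t. a scalar coordinate."""
    orig = get()
    set_(orig + h)
    up = energy_fn()
    set_(orig - h)
    um = energy_fn()
    set_(orig)
    return -(up - um) / (2 * h)
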