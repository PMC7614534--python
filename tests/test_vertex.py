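"""Vertex-model mechanics, topological moves and the sorting metric."""

import numpy as np
import pytest

from conftest import mesh_with_cells, perturb

from tissuesim.cells import Cell, CellCycleState, CellPopulation, CellStateError, CycleParameters
from tissuesim.geometry import Node, VertexElement, VertexMesh
from tissuesim.vertex import (
    UndefinedMetricError,
    VertexParameters,
    divide_element,
    find_t1_edges,
    heterotypic_fraction,
    nodal_forces,
    t1_swap,
    t2_remove,
    tissue_energy,
)

HEX_AREA = 3 * np.sqrt(3) / 2


def typed_params(**kw):
    gamma = kw.pop("gamma", None)
    if gamma is None:
        gamma = np.zeros((3, 3))
    return VertexParameters(gamma=gamma, **kw)


class TestTissueEnergy:
    def test_relaxed_hexagon_with_no_tension_has_zero_energy(self):
        mesh, cells = mesh_with_cells(1, 1)
        p = typed_params(k_perimeter=0.0)
        assert tissue_energy(mesh, cells, p) == pytest.approx(0.0, abs=1e-12)

    def test_unit_square_area_elasticity(self):
        mesh = VertexMesh(
            [Node(0, (0, 0)), Node(1, (1, 0)), Node(2, (1, 1)), Node(3, (0, 1))],
            [VertexElement(0, [0, 1, 2, 3])],
        )
        cells = CellPopulation([Cell(id=0, target_area=0.5)])
        p = typed_params(k_area=2.0, k_perimeter=0.0)
        # (2/2) * (1 - 0.5)^2
        assert tissue_energy(mesh, cells, p) == pytest.approx(0.25)

    def test_matches_term_by_term_recomputation(self, rng):
        mesh, cells = mesh_with_cells(2, 2, types="random", rng=rng)
        perturb(mesh, rng, 0.05)
        gamma = np.array([[0.02, 0.1, 0.2], [0.1, 0.03, 0.2], [0.2, 0.2, 0.0]])
        p = typed_params(k_area=1.3, k_perimeter=0.07, gamma=gamma)
        # oracle: walk every element and every edge explicitly
        u = 0.0
        for eid, el in mesh.elements.items():
            pts = mesh.ring_coords(el)
            a = 0.5 * sum(
                pts[k][0] * pts[(k + 1) % len(pts)][1] - pts[(k + 1) % len(pts)][0] * pts[k][1]
                for k in range(len(pts))
            )
            per = sum(
                np.linalg.norm(pts[(k + 1) % len(pts)] - pts[k]) for k in range(len(pts))
            )
            u += 0.65 * (a - cells[eid].target_area) ** 2 + 0.035 * per**2
        for (a_, b_), (e1, e2) in mesh.edges().items():
            t1 = cells[e1].type_label
            t2 = cells[e2].type_label if e2 is not None else -1
            u += gamma[t1, t2] * mesh.edge_length(a_, b_)
        assert tissue_energy(mesh, cells, p) == pytest.approx(u, rel=1e-12)

    def test_element_without_cell_is_an_error(self, rng):
        mesh, cells = mesh_with_cells(2, 1)
        cells.remove(1)
        with pytest.raises(CellStateError):
            tissue_energy(mesh, cells, typed_params())


class TestNodalForces:
    def test_zero_at_energy_minimum(self):
        mesh, cells = mesh_with_cells(1, 1)
        p = typed_params(k_perimeter=0.0)
        forces = nodal_forces(mesh, cells, p)
        for f in forces.values():
            assert np.linalg.norm(f) < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_central_difference_gradient(self, seed):
        rng = np.random.default_rng(seed)
        mesh, cells = mesh_with_cells(2, 2, types="random", rng=rng)
        perturb(mesh, rng, 0.08)
        gamma = np.array([[0.02, 0.12, 0.2], [0.12, 0.02, 0.2], [0.2, 0.2, 0.0]])
        p = typed_params(k_area=1.0, k_perimeter=0.04, gamma=gamma)
        forces = nodal_forces(mesh, cells, p)
        h = 1e-6
        for nid in mesh.nodes:
            for d in range(2):
                orig = mesh.nodes[nid].position.copy()
                step = np.zeros(2)
                step[d] = h
                mesh.nodes[nid].position = orig + step
                up = tissue_energy(mesh, cells, p)
                mesh.nodes[nid].position = orig - step
                um = tissue_energy(mesh, cells, p)
                mesh.nodes[nid].position = orig
                num = -(up - um) / (2 * h)
                assert forces[nid][d] == pytest.approx(num, rel=1e-5, abs=1e-8)

    def test_total_force_vanishes_by_translation_invariance(self, rng):
        mesh, cells = mesh_with_cells(3, 3, types="random", rng=rng)
        perturb(mesh, rng, 0.1)
        gamma = np.array([[0.05, 0.15, 0.2], [0.15, 0.05, 0.2], [0.2, 0.2, 0.0]])
        forces = nodal_forces(mesh, cells, typed_params(k_perimeter=0.05, gamma=gamma))
        assert np.linalg.norm(sum(forces.values())) < 1e-10


def shrink_interior_edge(mesh, factor):
    """Shrink the first interior edge whose endpoints both have flank elements."""
    for (a, b), (e1, e2) in sorted(mesh.edges().items()):
        if e2 is None:
            continue
        wa = [el.id for el in mesh.elements.values() if a in el.node_ids and b not in el.node_ids]
        wb = [el.id for el in mesh.elements.values() if b in el.node_ids and a not in el.node_ids]
        if wa and wb:
            pa, pb = mesh.nodes[a].position, mesh.nodes[b].position
            mid = 0.5 * (pa + pb)
            mesh.nodes[a].position = mid + factor * (pa - mid)
            mesh.nodes[b].position = mid + factor * (pb - mid)
            return (a, b), (e1, e2), (wa[0], wb[0])
    raise AssertionError("no swappable interior edge")


def adjacency(mesh):
    pairs = set()
    for (a, b), (e1, e2) in mesh.edges().items():
        if e2 is not None:
            pairs.add((min(e1, e2), max(e1, e2)))
    return pairs


class TestT1Swap:
    def test_adjacency_changes_by_predicted_pattern(self):
        mesh, cells = mesh_with_cells(2, 2)
        edge, (e1, e2), (fa, fb) = shrink_interior_edge(mesh, 0.04)
        before = adjacency(mesh)
        assert t1_swap(mesh, edge, typed_params(d_t1=0.1))
        mesh.validate()
        after = adjacency(mesh)
        lost = before - after
        gained = after - before
        assert lost == {(min(e1, e2), max(e1, e2))}
        assert gained == {(min(fa, fb), max(fa, fb))}

    def test_counts_conserved_and_separation_applied(self):
        mesh, cells = mesh_with_cells(2, 2)
        edge, _, _ = shrink_interior_edge(mesh, 0.04)
        nn, ne = len(mesh.nodes), len(mesh.elements)
        p = typed_params(d_t1=0.1, t1_separation_ratio=1.5)
        assert t1_swap(mesh, edge, p)
        assert (len(mesh.nodes), len(mesh.elements)) == (nn, ne)
        assert mesh.edge_length(*edge) == pytest.approx(1.5 * 0.1)

    def test_threshold_is_strict(self):
        mesh, cells = mesh_with_cells(2, 2)
        edge, _, _ = shrink_interior_edge(mesh, 1.0)
        length = mesh.edge_length(*edge)
        assert not t1_swap(mesh, edge, typed_params(d_t1=length))

    def test_detected_edges_are_only_short_interior_ones(self):
        mesh, cells = mesh_with_cells(2, 2)
        p = typed_params(d_t1=0.1)
        assert find_t1_edges(mesh, p) == []
        edge, _, _ = shrink_interior_edge(mesh, 0.04)
        assert find_t1_edges(mesh, p) == [tuple(sorted(edge))]


def t2_fixture():
    """Small interior triangle whose three neighbours tile a hexagon with it."""
    r = 0.06
    tri = [
        Node(k, (r * np.cos(a), r * np.sin(a)))
        for k, a in enumerate(np.deg2rad([0, 120, 240]))
    ]
    hexagon = [
        Node(3 + k, (np.cos(a), np.sin(a))) for k, a in enumerate(np.deg2rad(np.arange(0, 360, 60)))
    ]
    elements = [
        VertexElement(0, [0, 1, 2]),
        VertexElement(1, [0, 3, 4, 5, 1]),
        VertexElement(2, [1, 5, 6, 7, 2]),
        VertexElement(3, [2, 7, 8, 3, 0]),
    ]
    mesh = VertexMesh(tri + hexagon, elements)
    mesh.validate()
    cells = CellPopulation([Cell(id=i, target_area=1.0) for i in range(4)])
    return mesh, cells


class TestT2Remove:
    def test_counting_and_cell_removal(self):
        mesh, cells = t2_fixture()
        p = typed_params(a_t2=0.1)
        assert mesh.element_area(0) < 0.1
        assert t2_remove(mesh, 0, cells, p)
        mesh.validate()
        assert len(mesh.elements) == 3
        assert len(mesh.nodes) == 7  # 3 triangle nodes replaced by 1
        assert 0 not in cells

    def test_area_bookkeeping(self):
        mesh, cells = t2_fixture()
        removed = mesh.element_area(0)
        total_before = mesh.total_area()
        t2_remove(mesh, 0, cells, typed_params(a_t2=0.1))
        assert abs(mesh.total_area() - total_before) <= removed + 1e-12

    def test_large_or_nontriangular_elements_left_alone(self):
        mesh, cells = t2_fixture()
        assert not t2_remove(mesh, 1, cells, typed_params(a_t2=0.1))  # quad
        assert not t2_remove(mesh, 0, cells, typed_params(a_t2=0.001))  # big enough


class TestDivideElement:
    def make_ready(self, cells, cid):
        cells[cid].cycle = CellCycleState(model_kind="uniform", g1=5.0, ready=True)

    def test_daughters_partition_parent(self, rng):
        mesh, cells = mesh_with_cells(2, 2)
        perturb(mesh, rng, 0.05)
        self.make_ready(cells, 0)
        parent_area = mesh.element_area(0)
        ne = len(mesh.elements)
        ids = divide_element(mesh, 0, cells, CycleParameters(), rng, t=1.0)
        assert ids is not None
        mesh.validate()
        assert len(mesh.elements) == ne + 1
        d1, d2 = ids
        assert len(mesh.elements[d1].node_ids) >= 3
        assert len(mesh.elements[d2].node_ids) >= 3
        assert mesh.element_area(d1) + mesh.element_area(d2) == pytest.approx(
            parent_area, abs=1e-9
        )

    def test_axis_through_opposite_vertices_gives_equal_daughters(self, rng):
        mesh, cells = mesh_with_cells(1, 1)
        self.make_ready(cells, 0)
        # regular pointy-top hexagon: horizontal axis crosses two opposite edges
        ids = divide_element(
            mesh, 0, cells, CycleParameters(), rng, t=0.0, axis=np.array([1.0, 0.0])
        )
        assert ids is not None
        a1, a2 = mesh.element_area(ids[0]), mesh.element_area(ids[1])
        assert a1 == pytest.approx(a2, abs=1e-9)
        assert a1 + a2 == pytest.approx(HEX_AREA, abs=1e-9)

    def test_requires_ready_cell(self, rng):
        mesh, cells = mesh_with_cells(1, 1)
        with pytest.raises(CellStateError):
            divide_element(mesh, 0, cells, CycleParameters(), rng, t=0.0)


class TestHeterotypicFraction:
    def test_monotypic_tissue_is_zero(self, rng):
        mesh, cells = mesh_with_cells(3, 3)
        assert heterotypic_fraction(mesh, cells) == 0.0

    def test_single_element_undefined(self):
        mesh, cells = mesh_with_cells(1, 1)
        with pytest.raises(UndefinedMetricError):
            heterotypic_fraction(mesh, cells)

    def test_matches_explicit_edge_walk(self, rng):
        mesh, cells = mesh_with_cells(4, 4, types="random", rng=rng)
        hetero = total = 0.0
        for (a, b), (e1, e2) in mesh.edges().items():
            if e2 is None:
                continue
            length = np.linalg.norm(mesh.nodes[a].position - mesh.nodes[b].position)
            total += length
            if cells[e1].type_label != cells[e2].type_label:
                hetero += length
        assert heterotypic_fraction(mesh, cells) == pytest.approx(hetero / total, rel=1e-12)

    def test_alternating_columns(self):
        mesh, _ = mesh_with_cells(4, 1)
        cells = CellPopulation(
            [Cell(id=e, type_label=e % 2, target_area=1.0) for e in sorted(mesh.elements)]
        )
        # a 4x1 strip has 3 interior interfaces, all heterotypic under alternation
        assert heterotypic_fraction(mesh, cells) == pytest.approx(1.0)


def test_quasistatic_relaxation_energy_descent(rng):
    """Perturbed honeycomb relaxes monotonically under gradient descent at dt=0.01."""
    mesh, cells = mesh_with_cells(4, 4)
    perturb(mesh, rng, 0.08)
    gamma = np.full((3, 3), 0.0)
    gamma[-1, :] = gamma[:, -1] = 0.05
    gamma[-1, -1] = 0.0
    p = typed_params(k_area=1.0, k_perimeter=0.02, gamma=gamma, dt=0.01)
    energies = [tissue_energy(mesh, cells, p)]
    for _ in range(500):
        forces = nodal_forces(mesh, cells, p)
        for nid in sorted(mesh.nodes):
            mesh.nodes[nid].position = mesh.nodes[nid].position + (p.dt / p.drag) * forces[nid]
        energies.append(tissue_energy(mesh, cells, p))
    diffs = np.diff(energies)
    assert np.all(diffs <= 1e-12)
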