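"""Vertex-model (VM) mechanics.

Each cell is a polygon sharing edges and vertices with its neighbours; the
tissue evolves by overdamped gradient descent on the energy

    U = sum_i  k_area/2 * (A_i - A0_i)^2
      + sum_i  k_perimeter/2 * P_i^2
      + sum_edges  gamma(type_left, type_right) * l_edge

where the line-tension coefficient gamma is a symmetric matrix over cell
types with one extra index for the tissue boundary ("medium").  Making the
tension depend on the flanking cell types is what turns differential
adhesion into spontaneous cell sorting.

Topological moves keep the polygonal tiling well-formed while cells
rearrange: a T1 swap exchanges neighbour relationships when an edge shrinks
below a threshold, and a T2 transition removes a collapsing triangular cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cells import Cell, CellPopulation, CellStateError, make_daughters
from .geometry import InvalidGeometryError, VertexElement, VertexMesh, centroid, signed_area

__all__ = [
    "VertexParameters",
    "UndefinedMetricError",
    "tissue_energy",
    "nodal_forces",
    "t1_swap",
    "find_t1_edges",
    "t2_remove",
    "divide_element",
    "heterotypic_fraction",
]

log = logging.getLogger(__name__)

MEDIUM = -1  # type index used for the tissue boundary in the gamma matrix


class UndefinedMetricError(RuntimeError):
    """The requested tissue metric is undefined for this configuration."""


@dataclass
class VertexParameters:
    """Vertex-model parameters, in units of one cell diameter and one hour.

    ``gamma`` is indexed by cell-type pair; row/column -1 (the last index) is
    the medium, used for edges on the tissue boundary.  Defaults are chosen
    for numerical robustness on honeycomb tissues with unit edges; they are
    conventions of this package, not canonical values.
    """

    k_area: float = 1.0
    k_perimeter: float = 0.02
    gamma: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    d_t1: float = 0.1
    t1_separation_ratio: float = 1.5
    a_t2: float = 0.1
    drag: float = 1.0
    dt: float = 0.01
    noise: float = 0.0  # isotropic random nodal displacement per step

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.k_area <= 0 or self.drag <= 0 or self.dt <= 0:
            raise ValueError("k_area, drag and dt must be > 0")
        if self.d_t1 < 0 or self.a_t2 < 0:
            raise ValueError("d_t1 and a_t2 must be >= 0")
        if not np.allclose(self.gamma, self.gamma.T):
            raise ValueError("gamma must be symmetric")

    def tension(self, type_a: int, type_b: int) -> float:
        return float(self.gamma[type_a, type_b])


def _edge_types(
    mesh: VertexMesh, cells: CellPopulation
) -> list[tuple[int, int, int, int]]:
    """(node_a, node_b, type_left, type_right) per undirected edge; MEDIUM on boundary."""
    out = []
    for (a, b), (el, opp) in mesh.edges().items():
        ta = _cell_type(cells, el)
        tb = _cell_type(cells, opp) if opp is not None else MEDIUM
        out.append((a, b, ta, tb))
    return out


def _cell_type(cells: CellPopulation, element_id: int) -> int:
    if element_id not in cells:
        raise CellStateError(f"element {element_id} has no associated cell")
    return cells[element_id].type_label


def tissue_energy(mesh: VertexMesh, cells: CellPopulation, params: VertexParameters) -> float:
    """Total tissue energy (area elasticity + perimeter contractility + line tension)."""
    u = 0.0
    for eid in mesh.elements:
        cell = cells[eid] if eid in cells else None
        if cell is None:
            raise CellStateError(f"element {eid} has no associated cell")
        a = mesh.element_area(eid)
        p = mesh.element_perimeter(eid)
        u += 0.5 * params.k_area * (a - cell.target_area) ** 2
        u += 0.5 * params.k_perimeter * p**2
    for a, b, ta, tb in _edge_types(mesh, cells):
        u += params.tension(ta, tb) * mesh.edge_length(a, b)
    return u


def nodal_forces(
    mesh: VertexMesh, cells: CellPopulation, params: VertexParameters
) -> dict[int, np.ndarray]:
    """Analytic force -dU/dx on every node.

    Area gradients use the cross-product of the two ring neighbours of each
    vertex; perimeter and line-tension gradients use unit edge vectors.
    """
    forces = {nid: np.zeros(2) for nid in mesh.nodes}
    for eid, el in mesh.elements.items():
        cell = cells[eid] if eid in cells else None
        if cell is None:
            raise CellStateError(f"element {eid} has no associated cell")
        ring = el.node_ids
        pts = mesh.ring_coords(el)
        area = signed_area(pts)
        perim = float(np.sum(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)))
        n = len(ring)
        ka_term = params.k_area * (area - cell.target_area)
        kp_term = params.k_perimeter * perim
        for k in range(n):
            prev_p = pts[k - 1]
            next_p = pts[(k + 1) % n]
            # dA/dx_k = 0.5 * (y_next - y_prev, x_prev - x_next) for a CCW ring
            dA = 0.5 * np.array([next_p[1] - prev_p[1], prev_p[0] - next_p[0]])
            e_prev = pts[k] - prev_p
            e_next = pts[k] - next_p
            lp = np.linalg.norm(e_prev)
            ln = np.linalg.norm(e_next)
            dP = np.zeros(2)
            if lp > 1e-14:
                dP += e_prev / lp
            if ln > 1e-14:
                dP += e_next / ln
            forces[ring[k]] -= ka_term * dA + kp_term * dP
    for a, b, ta, tb in _edge_types(mesh, cells):
        g = params.tension(ta, tb)
        if g == 0.0:
            continue
        r = mesh.nodes[a].position - mesh.nodes[b].position
        length = np.linalg.norm(r)
        if length < 1e-14:
            continue
        grad = r / length  # d l / d x_a
        forces[a] -= g * grad
        forces[b] += g * grad
    return forces


# ---------------------------------------------------------------------------
# topological moves


def find_t1_edges(mesh: VertexMesh, params: VertexParameters) -> list[tuple[int, int]]:
    """Interior edges strictly shorter than the T1 threshold, in fixed id order."""
    short = []
    for (a, b), (_, opp) in sorted(mesh.edges().items()):
        if opp is None:
            continue
        if mesh.edge_length(a, b) < params.d_t1:
            short.append((a, b))
    return short


def t1_swap(mesh: VertexMesh, edge: tuple[int, int], params: VertexParameters) -> bool:
    """Perform a T1 edge rearrangement in place; return whether it happened.

    The two elements sharing the edge lose it; the two elements flanking its
    endpoints gain it.  The nodes are repositioned perpendicular to the old
    edge through its midpoint, at separation
    ``t1_separation_ratio * d_t1``.  A swap that would leave any element with
    fewer than 3 nodes is skipped (and logged).
    """
    a, b = edge
    if mesh.edge_length(a, b) >= params.d_t1:
        return False
    directed = mesh.directed_edges()
    if (a, b) not in directed or (b, a) not in directed:
        log.info("T1 on (%d, %d) skipped: edge not interior", a, b)
        return False
    el_ab = mesh.elements[directed[(a, b)]]  # traverses a -> b
    el_ba = mesh.elements[directed[(b, a)]]
    with_a = [el for el in mesh.elements.values() if a in el.node_ids and b not in el.node_ids]
    with_b = [el for el in mesh.elements.values() if b in el.node_ids and a not in el.node_ids]
    if len(with_a) > 1 or len(with_b) > 1:
        log.info("T1 on (%d, %d) skipped: non-manifold surroundings", a, b)
        return False
    if len(el_ab.node_ids) <= 3 or len(el_ba.node_ids) <= 3:
        log.info("T1 on (%d, %d) skipped: would create a <3-node element", a, b)
        return False

    pa, pb = mesh.nodes[a].position, mesh.nodes[b].position
    mid = 0.5 * (pa + pb)
    u = pb - pa
    norm = np.linalg.norm(u)
    u = u / norm if norm > 1e-14 else np.array([1.0, 0.0])
    perp = np.array([-u[1], u[0]])  # CCW rotation: points into el_ab's interior
    sep = params.t1_separation_ratio * params.d_t1
    mesh.nodes[a].position = mid + 0.5 * sep * perp
    mesh.nodes[b].position = mid - 0.5 * sep * perp

    # elements traversing the edge keep the node on their interior side
    el_ab.node_ids.remove(b)
    el_ba.node_ids.remove(a)
    # flanking elements gain the opposite node, inserted just before their
    # own so both daughters traverse the new edge in opposite directions
    for el in with_a:
        el.node_ids.insert(el.node_ids.index(a), b)
    for el in with_b:
        el.node_ids.insert(el.node_ids.index(b), a)
    return True


def t2_remove(
    mesh: VertexMesh, element_id: int, cells: CellPopulation, params: VertexParameters
) -> bool:
    """Remove a collapsing triangular element (T2 transition) in place.

    The triangle's three nodes are replaced by one node at its centroid;
    neighbouring elements are re-wired through the new node and the
    associated cell leaves the population.  Returns whether removal happened.
    """
    el = mesh.elements[element_id]
    if len(el.node_ids) != 3:
        log.info("T2 on element %d skipped: not a triangle", element_id)
        return False
    if mesh.element_area(element_id) >= params.a_t2:
        return False
    from .geometry import Node

    new_pos = centroid(mesh.ring_coords(el))
    new_id = mesh.next_node_id()
    old_ids = set(el.node_ids)
    mesh.nodes[new_id] = Node(new_id, new_pos)
    del mesh.elements[element_id]
    for other in mesh.elements.values():
        if old_ids.isdisjoint(other.node_ids):
            continue
        ring = [new_id if nid in old_ids else nid for nid in other.node_ids]
        deduped = [nid for k, nid in enumerate(ring) if nid != ring[k - 1]]
        if len(deduped) < 3:
            raise InvalidGeometryError(
                f"T2 removal of element {element_id} would degenerate element {other.id}"
            )
        other.node_ids = deduped
    for nid in old_ids:
        del mesh.nodes[nid]
    if element_id in cells:
        cells.remove(element_id)
    return True


def find_t2_elements(mesh: VertexMesh, params: VertexParameters) -> list[int]:
    return [
        eid
        for eid in sorted(mesh.elements)
        if len(mesh.elements[eid].node_ids) == 3 and mesh.element_area(eid) < params.a_t2
    ]


# ---------------------------------------------------------------------------
# division


def short_axis(pts: np.ndarray) -> np.ndarray:
    """Unit direction of the shortest principal axis of a polygon's vertex cloud."""
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / len(pts)
    vals, vecs = np.linalg.eigh(cov)
    return vecs[:, 0]  # eigenvector of the smallest second moment


def _segment_intersection(p, d, q0, q1):
    """Intersection of the infinite line p + s*d with segment [q0, q1].

    Returns (s, u, point) with u in (0, 1) strictly inside the segment,
    or None."""
    e = q1 - q0
    denom = d[0] * e[1] - d[1] * e[0]
    if abs(denom) < 1e-12:
        return None
    w = q0 - p
    s = (w[0] * e[1] - w[1] * e[0]) / denom
    u = (w[0] * d[1] - w[1] * d[0]) / denom
    if 1e-9 < u < 1 - 1e-9:
        return s, u, q0 + u * e
    return None


def divide_element(
    mesh: VertexMesh,
    element_id: int,
    cells: CellPopulation,
    cycle_params,
    rng: np.random.Generator,
    t: float,
    axis: np.ndarray | str = "short-axis",
) -> tuple[int, int] | None:
    """Split a division-ready element through its centroid.

    The split line runs along ``axis`` (default: the shortest principal axis
    of the element's second-moment tensor, i.e. perpendicular to the cell's
    elongation).  Two new nodes are inserted where the line crosses the
    element boundary — and into any neighbouring elements sharing those
    edges, so the edge-sharing invariant is preserved.  The parent cell is
    replaced by two daughters; returns their (element) ids, or None if the
    division had to be deferred because the cut was degenerate.
    """
    el = mesh.elements[element_id]
    parent = cells[element_id]
    if not parent.cycle.ready:
        raise CellStateError(f"cell {element_id} is not division-ready")
    pts = mesh.ring_coords(el)
    if isinstance(axis, str):
        direction = short_axis(pts)
    else:
        direction = np.asarray(axis, dtype=float)
        direction = direction / np.linalg.norm(direction)
    c = centroid(pts)
    n = len(el.node_ids)
    hits = []  # (ring edge index k, u along that edge, point)
    for k in range(n):
        res = _segment_intersection(c, direction, pts[k], pts[(k + 1) % n])
        if res is not None:
            hits.append((k, res[1], res[2]))
    if len(hits) != 2:
        log.info("division of element %d deferred: %d boundary crossings", element_id, len(hits))
        return None

    from .geometry import Node

    directed = mesh.directed_edges()
    new_node_ids = []
    # insert nodes from the highest ring index down so earlier indices stay valid
    for k, u, point in sorted(hits, key=lambda h: -h[0]):
        nid = mesh.next_node_id()
        mesh.nodes[nid] = Node(nid, point)
        a_id, b_id = el.node_ids[k], el.node_ids[(k + 1) % n]
        el.node_ids.insert(k + 1, nid)
        opp = directed.get((b_id, a_id))
        if opp is not None and opp != element_id:
            other = mesh.elements[opp]
            other.node_ids.insert(other.node_ids.index(b_id) + 1, nid)
        new_node_ids.append(nid)

    i1 = el.node_ids.index(new_node_ids[0])
    i2 = el.node_ids.index(new_node_ids[1])
    if i1 > i2:
        i1, i2 = i2, i1
    ring_a = el.node_ids[i1 : i2 + 1]
    ring_b = el.node_ids[i2:] + el.node_ids[: i1 + 1]
    if len(ring_a) < 3 or len(ring_b) < 3:
        log.info("division of element %d deferred: degenerate daughter ring", element_id)
        # roll back node insertions
        for nid in new_node_ids:
            for other in mesh.elements.values():
                if nid in other.node_ids:
                    other.node_ids.remove(nid)
            del mesh.nodes[nid]
        return None

    d1, d2 = make_daughters(parent, t, cells, cycle_params, rng)
    del mesh.elements[element_id]
    mesh.elements[d1.id] = VertexElement(d1.id, ring_a)
    mesh.elements[d2.id] = VertexElement(d2.id, ring_b)
    return d1.id, d2.id


# ---------------------------------------------------------------------------
# sorting metric


def heterotypic_fraction(mesh: VertexMesh, cells: CellPopulation) -> float:
    """Length fraction of interior edges whose flanking cells differ in type.

    Raises :class:`UndefinedMetricError` when the tissue has no interior
    edges (e.g. a single cell)."""
    total = 0.0
    hetero = 0.0
    for a, b, ta, tb in _edge_types(mesh, cells):
        if tb == MEDIUM:
            continue
        length = mesh.edge_length(a, b)
        total += length
        if ta != tb:
            hetero += length
    if total == 0.0:
        raise UndefinedMetricError("no interior edges: heterotypic fraction undefined")
    return hetero / total
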