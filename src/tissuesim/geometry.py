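"""Planar geometric kernel.

Polygon measures (shoelace area, perimeter, centroid), Delaunay/Voronoi
tessellation of point clouds, and generators for the initial conditions used
by the on- and off-lattice frameworks: honeycomb vertex meshes and lattice
"blobs".

All coordinates are dimensionless, with one typical cell diameter as the
length unit.  Ids are 0-based and dense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from scipy.spatial import QhullError

__all__ = [
    "InvalidGeometryError",
    "TessellationError",
    "ConfigError",
    "Node",
    "VertexElement",
    "VertexMesh",
    "Lattice",
    "BoundingBox",
    "signed_area",
    "perimeter",
    "centroid",
    "delaunay_pairs",
    "voronoi_regions",
    "build_honeycomb_mesh",
    "build_lattice_blob",
]

#: Two nodes closer than this (in units of one cell diameter) are considered
#: coincident when validating a mesh.
NODE_MERGE_TOLERANCE = 1e-10


class InvalidGeometryError(ValueError):
    """A polygon or mesh violates a geometric precondition."""


class TessellationError(ValueError):
    """Delaunay/Voronoi construction is impossible (too few or collinear points)."""


class ConfigError(ValueError):
    """A generator was called with unusable arguments."""


# ---------------------------------------------------------------------------
# polygon measures


def _as_ring(ring) -> np.ndarray:
    pts = np.asarray(ring, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InvalidGeometryError(
            f"a polygon ring needs >=3 two-dimensional points, got shape {pts.shape}"
        )
    if not np.all(np.isfinite(pts)):
        raise InvalidGeometryError("non-finite coordinate in polygon ring")
    return pts


def signed_area(ring) -> float:
    """Shoelace signed area: positive for counter-clockwise rings."""
    pts = _as_ring(ring)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter(ring) -> float:
    """Sum of consecutive edge lengths, closing the ring."""
    pts = _as_ring(ring)
    return float(np.sum(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)))


def centroid(ring) -> np.ndarray:
    """Area-weighted polygon centroid.

    Raises :class:`InvalidGeometryError` on (numerically) zero-area rings,
    for which the centroid is undefined.
    """
    pts = _as_ring(ring)
    a = signed_area(pts)
    if abs(a) < 1e-14:
        raise InvalidGeometryError("centroid of a degenerate (zero-area) ring")
    nxt = np.roll(pts, -1, axis=0)
    cross = pts[:, 0] * nxt[:, 1] - nxt[:, 0] * pts[:, 1]
    cx = np.sum((pts[:, 0] + nxt[:, 0]) * cross) / (6.0 * a)
    cy = np.sum((pts[:, 1] + nxt[:, 1]) * cross) / (6.0 * a)
    return np.array([cx, cy])


# ---------------------------------------------------------------------------
# tessellation


def _check_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise TessellationError(f"expected an (n, 2) point array, got shape {pts.shape}")
    if pts.shape[0] < 3:
        raise TessellationError("tessellation needs at least 3 points")
    return pts


def delaunay_pairs(points) -> set[tuple[int, int]]:
    """Unordered index pairs of points sharing a Delaunay edge.

    For points in general position this equals the empty-circumcircle
    neighbour graph.  Four exactly cocircular points may resolve either
    diagonal; both are valid tessellations.
    """
    pts = _check_points(points)
    try:
        tri = Delaunay(pts)
    except QhullError as exc:  # collinear input, degenerate hull
        raise TessellationError(f"Delaunay triangulation failed: {exc}") from exc
    pairs: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for k in range(3):
            i, j = int(simplex[k]), int(simplex[(k + 1) % 3])
            pairs.add((min(i, j), max(i, j)))
    return pairs


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned clipping window."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise InvalidGeometryError("bounding box must have positive extent")

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    def corners(self) -> np.ndarray:
        return np.array(
            [
                [self.xmin, self.ymin],
                [self.xmax, self.ymin],
                [self.xmax, self.ymax],
                [self.xmin, self.ymax],
            ]
        )

    def contains(self, points) -> bool:
        pts = np.asarray(points, dtype=float)
        return bool(
            np.all(pts[:, 0] >= self.xmin)
            and np.all(pts[:, 0] <= self.xmax)
            and np.all(pts[:, 1] >= self.ymin)
            and np.all(pts[:, 1] <= self.ymax)
        )


def _clip_halfplane(poly: np.ndarray, n: np.ndarray, c: float) -> np.ndarray:
    """Sutherland-Hodgman clip of `poly` to the half-plane n.x <= c."""
    out: list[np.ndarray] = []
    m = len(poly)
    for i in range(m):
        p, q = poly[i], poly[(i + 1) % m]
        dp, dq = float(n @ p) - c, float(n @ q) - c
        if dp <= 0:
            out.append(p)
            if dq > 0:
                out.append(p + (q - p) * (dp / (dp - dq)))
        elif dq <= 0:
            out.append(p + (q - p) * (dp / (dp - dq)))
    return np.array(out) if out else np.empty((0, 2))


def voronoi_regions(points, box: BoundingBox) -> list[np.ndarray]:
    """One clipped Voronoi polygon (CCW ring) per generator point.

    Each region is the intersection of the box with the perpendicular-bisector
    half-planes against every other generator.  Unbounded regions are always
    clipped to the box, never dropped; together the regions partition the box.
    """
    pts = _check_points(points)
    if not box.contains(pts):
        raise InvalidGeometryError("bounding box does not contain all points")
    # require a valid triangulation to exist (mirrors delaunay_pairs errors)
    delaunay_pairs(pts)
    regions = []
    for i, p in enumerate(pts):
        poly = box.corners()
        for j, q in enumerate(pts):
            if i == j:
                continue
            n = q - p
            c = float(n @ (p + q)) / 2.0
            poly = _clip_halfplane(poly, n, c)
            if len(poly) == 0:
                break
        if len(poly) < 3:
            raise InvalidGeometryError(f"Voronoi region of point {i} degenerated under clipping")
        if signed_area(poly) < 0:
            poly = poly[::-1]
        regions.append(poly)
    return regions


# single-point convenience used by writers (a lone cell owns the whole box)
def voronoi_regions_or_box(points, box: BoundingBox) -> list[np.ndarray]:
    pts = np.asarray(points, dtype=float)
    if len(pts) == 1:
        return [box.corners()]
    if len(pts) == 2:
        out = []
        for i in (0, 1):
            p, q = pts[i], pts[1 - i]
            n = q - p
            c = float(n @ (p + q)) / 2.0
            poly = _clip_halfplane(box.corners(), n, c)
            if signed_area(poly) < 0:
                poly = poly[::-1]
            out.append(poly)
        return out
    return voronoi_regions(pts, box)


# ---------------------------------------------------------------------------
# vertex meshes


@dataclass
class Node:
    id: int
    position: np.ndarray
    is_boundary: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (2,) or not np.all(np.isfinite(self.position)):
            raise InvalidGeometryError(f"node {self.id}: bad position {self.position}")


@dataclass
class VertexElement:
    """A polygonal cell outline: an ordered (counter-clockwise) ring of node ids."""

    id: int
    node_ids: list[int]

    def __post_init__(self):
        self.node_ids = [int(i) for i in self.node_ids]
        if len(self.node_ids) < 3:
            raise InvalidGeometryError(f"element {self.id}: ring has <3 nodes")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise InvalidGeometryError(f"element {self.id}: repeated node in ring")


class VertexMesh:
    """Nodes plus polygonal elements with shared edges.

    Interior edges are traversed by exactly two elements, in opposite
    directions; boundary edges by exactly one.  Element rings are stored
    counter-clockwise; clockwise input is repaired by reversal at
    construction.
    """

    def __init__(self, nodes: list[Node], elements: list[VertexElement]):
        self.nodes: dict[int, Node] = {n.id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise InvalidGeometryError("duplicate node ids")
        self.elements: dict[int, VertexElement] = {}
        for el in elements:
            if el.id in self.elements:
                raise InvalidGeometryError(f"duplicate element id {el.id}")
            if signed_area(self.ring_coords(el)) < 0:
                el.node_ids = el.node_ids[::-1]
            self.elements[el.id] = el

    # -- queries ------------------------------------------------------------

    def ring_coords(self, element: VertexElement) -> np.ndarray:
        return np.array([self.nodes[i].position for i in element.node_ids])

    def element_area(self, element_id: int) -> float:
        return signed_area(self.ring_coords(self.elements[element_id]))

    def element_perimeter(self, element_id: int) -> float:
        return perimeter(self.ring_coords(self.elements[element_id]))

    def total_area(self) -> float:
        return sum(self.element_area(i) for i in self.elements)

    def directed_edges(self) -> dict[tuple[int, int], int]:
        """Map each directed edge (a, b) to the element id traversing it."""
        out: dict[tuple[int, int], int] = {}
        for el in self.elements.values():
            ring = el.node_ids
            for k in range(len(ring)):
                e = (ring[k], ring[(k + 1) % len(ring)])
                if e in out:
                    raise InvalidGeometryError(
                        f"directed edge {e} traversed by elements {out[e]} and {el.id}"
                    )
                out[e] = el.id
        return out

    def edges(self) -> dict[tuple[int, int], tuple[int, int | None]]:
        """Map each undirected edge (min, max) to its (element, opposite element)
        pair; the second entry is None for boundary edges."""
        directed = self.directed_edges()
        out: dict[tuple[int, int], tuple[int, int | None]] = {}
        for (a, b), el in directed.items():
            key = (min(a, b), max(a, b))
            if key in out:
                continue
            opp = directed.get((b, a))
            out[key] = (el, opp)
        return out

    def edge_length(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self.nodes[a].position - self.nodes[b].position))

    def elements_containing(self, node_id: int) -> list[int]:
        return [el.id for el in self.elements.values() if node_id in el.node_ids]

    def next_node_id(self) -> int:
        return max(self.nodes) + 1 if self.nodes else 0

    def next_element_id(self) -> int:
        return max(self.elements) + 1 if self.elements else 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Re-check all structural invariants; raise InvalidGeometryError on failure."""
        for el in self.elements.values():
            for nid in el.node_ids:
                if nid not in self.nodes:
                    raise InvalidGeometryError(f"element {el.id} references missing node {nid}")
            a = signed_area(self.ring_coords(el))
            if a <= 0:
                raise InvalidGeometryError(f"element {el.id} has non-positive area {a}")
        # directed_edges raises if any directed edge is traversed twice, which
        # covers both duplicate edges and same-direction (mis-oriented) sharing
        self.directed_edges()
        positions = np.array([n.position for n in self.nodes.values()])
        if len(positions) > 1:
            from scipy.spatial import cKDTree

            tree = cKDTree(positions)
            close = tree.query_pairs(NODE_MERGE_TOLERANCE)
            if close:
                raise InvalidGeometryError(f"{len(close)} node pairs closer than merge tolerance")

    def refresh_boundary_flags(self) -> None:
        """Mark nodes on boundary (single-traversal) edges."""
        for n in self.nodes.values():
            n.is_boundary = False
        for (a, b), (_, opp) in self.edges().items():
            if opp is None:
                self.nodes[a].is_boundary = True
                self.nodes[b].is_boundary = True


def build_honeycomb_mesh(nx: int, ny: int, edge: float = 1.0) -> VertexMesh:
    """Regular honeycomb of ``nx`` columns by ``ny`` rows of hexagonal cells.

    Adjacent hexagons share Node objects (not coordinate duplicates); every
    element has area 3*sqrt(3)/2 * edge**2.
    """
    if nx < 1 or ny < 1 or edge <= 0:
        raise ConfigError("honeycomb needs nx, ny >= 1 and edge > 0")
    w = np.sqrt(3.0) * edge  # pointy-top hexagon width
    # pointy-top hexagon: vertices at angles 30 + 60k degrees, circumradius=edge
    angles = np.deg2rad(30 + 60 * np.arange(6))
    hexagon = np.stack([edge * np.cos(angles), edge * np.sin(angles)], axis=1)
    key_to_id: dict[tuple[int, int], int] = {}
    nodes: list[Node] = []
    elements: list[VertexElement] = []
    scale = edge * 1e-6
    for row in range(ny):
        for col in range(nx):
            cx = col * w + (w / 2 if row % 2 else 0.0)
            cy = row * 1.5 * edge
            ring_ids = []
            for vx, vy in hexagon + np.array([cx, cy]):
                key = (round(vx / scale), round(vy / scale))
                nid = key_to_id.get(key)
                if nid is None:
                    nid = len(nodes)
                    key_to_id[key] = nid
                    nodes.append(Node(nid, np.array([vx, vy])))
                ring_ids.append(nid)
            elements.append(VertexElement(len(elements), ring_ids))
    mesh = VertexMesh(nodes, elements)
    mesh.refresh_boundary_flags()
    return mesh


# ---------------------------------------------------------------------------
# lattices


class Lattice:
    """Integer site grid mapping each site to a cell id (0 = empty/medium)."""

    VON_NEUMANN = ((1, 0), (-1, 0), (0, 1), (0, -1))
    MOORE = VON_NEUMANN + ((1, 1), (1, -1), (-1, 1), (-1, -1))

    def __init__(self, width: int, height: int, neighbourhood_order: str = "von_neumann"):
        if width < 1 or height < 1:
            raise ConfigError("lattice dimensions must be >= 1")
        if neighbourhood_order not in ("von_neumann", "moore"):
            raise ConfigError(f"unknown neighbourhood order {neighbourhood_order!r}")
        self.width = int(width)
        self.height = int(height)
        self.neighbourhood_order = neighbourhood_order
        # occupancy[x, y]; 0 is reserved for medium
        self.occupancy = np.zeros((self.width, self.height), dtype=np.int64)

    @property
    def offsets(self):
        return self.MOORE if self.neighbourhood_order == "moore" else self.VON_NEUMANN

    def in_bounds(self, x: int, y: int) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height

    def neighbours(self, x: int, y: int) -> list[tuple[int, int]]:
        """Neighbouring sites; edge sites simply have fewer (fixed boundaries)."""
        return [
            (x + dx, y + dy) for dx, dy in self.offsets if self.in_bounds(x + dx, y + dy)
        ]

    def sites_of(self, cell_id: int) -> np.ndarray:
        return np.argwhere(self.occupancy == cell_id)

    def cell_areas(self) -> dict[int, int]:
        """Site count per non-medium cell id."""
        ids, counts = np.unique(self.occupancy, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts) if i != 0}

    def copy(self) -> "Lattice":
        out = Lattice(self.width, self.height, self.neighbourhood_order)
        out.occupancy = self.occupancy.copy()
        return out


def _disc_sites(width: int, height: int, radius: float) -> np.ndarray:
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    xs, ys = np.meshgrid(np.arange(width), np.arange(height), indexing="ij")
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    return np.argwhere(mask)


def build_lattice_blob(
    width: int,
    height: int,
    radius: float,
    n_cells: int,
    mode: str,
    rng: np.random.Generator,
    neighbourhood_order: str | None = None,
) -> Lattice:
    """Disc-shaped initial condition for the lattice frameworks.

    CA mode: ``n_cells`` distinct sites inside the disc, one cell each.
    CP mode: the disc partitioned into ``n_cells`` 4-connected domains of
    as-equal-as-possible size, grown by balanced multi-source BFS.
    """
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    if cx - radius < -0.5 or cy - radius < -0.5 or cx + radius > width - 0.5 or cy + radius > height - 0.5:
        raise ConfigError("blob does not fit in the grid")
    order = neighbourhood_order or ("von_neumann" if mode == "CA" else "moore")
    lattice = Lattice(width, height, order)
    disc = _disc_sites(width, height, radius)
    if mode == "CA":
        if n_cells > len(disc):
            raise ConfigError(f"{n_cells} cells do not fit in a {len(disc)}-site disc")
        chosen = disc[rng.choice(len(disc), size=n_cells, replace=False)]
        for cid, (x, y) in enumerate(chosen, start=1):
            lattice.occupancy[x, y] = cid
    elif mode == "CP":
        if n_cells < 1 or n_cells > len(disc):
            raise ConfigError("n_cells out of range for disc")
        in_disc = {tuple(s) for s in map(tuple, disc)}
        seeds = disc[rng.choice(len(disc), size=n_cells, replace=False)]
        frontiers: list[list[tuple[int, int]]] = []
        sizes = np.zeros(n_cells, dtype=int)
        for cid, (x, y) in enumerate(seeds, start=1):
            lattice.occupancy[x, y] = cid
            sizes[cid - 1] = 1
            frontiers.append([(x, y)])
        # balanced growth: always extend the currently smallest domain
        remaining = len(disc) - n_cells
        while remaining > 0:
            grew = False
            for cid in (np.argsort(sizes) + 1):
                frontier = frontiers[cid - 1]
                while frontier:
                    x, y = frontier[0]
                    vacant = [
                        (nx_, ny_)
                        for dx, dy in Lattice.VON_NEUMANN
                        for nx_, ny_ in [(x + dx, y + dy)]
                        if (nx_, ny_) in in_disc and lattice.occupancy[nx_, ny_] == 0
                    ]
                    if vacant:
                        pick = vacant[rng.integers(len(vacant))]
                        lattice.occupancy[pick] = cid
                        frontier.append(pick)
                        sizes[cid - 1] += 1
                        remaining -= 1
                        grew = True
                        break
                    frontier.pop(0)
                if grew:
                    break
            if not grew:  # isolated vacant pockets cannot occur in a disc, but guard
                break
    else:
        raise ConfigError(f"unknown blob mode {mode!r}")
    return lattice
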