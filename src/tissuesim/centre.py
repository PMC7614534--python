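"""Off-lattice cell-centre frameworks.

Each cell is a point; mechanics act through pairwise linear (Hookean)
springs between neighbouring centres,

    F_ij = mu * (|r_ij| - s_ij(t)) * r_hat_ij,

attractive when stretched beyond the rest length, repulsive when
compressed.  Neighbours are defined either by a distance cutoff
("overlapping spheres", PM) or by shared Voronoi faces, i.e. Delaunay
edges ("Voronoi tessellation", VT).  Positions follow overdamped forward
Euler: x <- x + (dt/eta) * F.

After a division the sibling pair's rest length ramps linearly from
``newborn_separation`` to the mature ``rest_length`` over
``growth_duration``, after which the pair is indistinguishable from any
other neighbour pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cells import CellPopulation, CellStateError, make_daughters
from .geometry import TessellationError, delaunay_pairs

__all__ = [
    "CentrePopulation",
    "CentreParameters",
    "IntegrationError",
    "neighbour_pairs",
    "spring_forces",
    "step_positions",
    "divide_centre_cell",
]

log = logging.getLogger(__name__)


class IntegrationError(RuntimeError):
    """A non-finite force reached the integrator."""


@dataclass
class CentreParameters:
    stiffness: float = 15.0
    rest_length: float = 1.0
    growth_duration: float = 1.0
    newborn_separation: float = 0.3
    drag: float = 1.0
    dt: float = 0.005
    cutoff: float = 1.5  # interaction radius, overlapping_spheres mode

    def __post_init__(self):
        if min(self.stiffness, self.drag, self.dt) <= 0:
            raise ValueError("stiffness, drag and dt must be > 0")
        if not (0 < self.newborn_separation < self.rest_length):
            raise ValueError("need 0 < newborn_separation < rest_length")


class CentrePopulation:
    """One point per live cell plus a connectivity rule.

    ``positions`` maps cell id -> 2-vector.  ``sibling_since`` records the
    division time of recently divided pairs for rest-length ramping; entries
    expire once the ramp completes.
    """

    MODES = ("overlapping_spheres", "voronoi")

    def __init__(self, positions: dict[int, np.ndarray], connectivity_mode: str = "overlapping_spheres"):
        if connectivity_mode not in self.MODES:
            raise ValueError(f"unknown connectivity mode {connectivity_mode!r}")
        self.positions: dict[int, np.ndarray] = {
            int(k): np.asarray(v, dtype=float) for k, v in positions.items()
        }
        self.connectivity_mode = connectivity_mode
        self.sibling_since: dict[frozenset[int], float] = {}

    def ids(self) -> list[int]:
        return sorted(self.positions)

    def coords(self) -> np.ndarray:
        return np.array([self.positions[i] for i in self.ids()])

    def __len__(self) -> int:
        return len(self.positions)


def neighbour_pairs(pop: CentrePopulation, params: CentreParameters) -> set[tuple[int, int]]:
    """Unordered id pairs of interacting cells.

    Overlapping spheres: separation strictly below the cutoff radius.
    Voronoi: Delaunay edges of the centre positions (unrestricted; distant
    boundary neighbours are a documented limitation of this mode).
    """
    ids = pop.ids()
    if pop.connectivity_mode == "overlapping_spheres":
        if len(ids) < 2:
            return set()
        pts = pop.coords()
        tree = cKDTree(pts)
        pairs = set()
        for i, j in tree.query_pairs(params.cutoff):
            if np.linalg.norm(pts[i] - pts[j]) < params.cutoff:
                pairs.add((min(ids[i], ids[j]), max(ids[i], ids[j])))
        return pairs
    if len(ids) < 3:
        raise TessellationError("voronoi connectivity needs >= 3 cells")
    return {
        (min(ids[i], ids[j]), max(ids[i], ids[j]))
        for i, j in delaunay_pairs(pop.coords())
    }


def _rest_length(pair: frozenset[int], t: float, pop: CentrePopulation, params: CentreParameters) -> float:
    born = pop.sibling_since.get(pair)
    if born is None:
        return params.rest_length
    frac = (t - born) / params.growth_duration
    if frac >= 1.0:
        del pop.sibling_since[pair]  # ramp complete; ordinary pair from now on
        return params.rest_length
    frac = max(frac, 0.0)
    return params.newborn_separation + frac * (params.rest_length - params.newborn_separation)


def spring_forces(
    pop: CentrePopulation,
    pairs: set[tuple[int, int]],
    cells: CellPopulation,
    params: CentreParameters,
    t: float,
    rng: np.random.Generator | None = None,
) -> dict[int, np.ndarray]:
    """Pairwise Hookean forces; equal and opposite on the two cells of a pair.

    Coincident centres (separation < 1e-12) repel along a random direction
    (logged) so overlapping newborns always separate.
    """
    forces = {i: np.zeros(2) for i in pop.positions}
    for i, j in sorted(pairs):
        r = pop.positions[j] - pop.positions[i]
        dist = float(np.linalg.norm(r))
        if dist < 1e-12:
            log.warning("coincident cells %d and %d: applying random repulsion", i, j)
            theta = rng.uniform(0, 2 * np.pi) if rng is not None else 0.0
            unit = np.array([np.cos(theta), np.sin(theta)])
            f = params.stiffness * params.rest_length * unit
            forces[i] -= f
            forces[j] += f
            continue
        unit = r / dist
        s = _rest_length(frozenset((i, j)), t, pop, params)
        f = params.stiffness * (dist - s) * unit  # on i, toward j when stretched
        forces[i] += f
        forces[j] -= f
    return forces


def step_positions(
    pop: CentrePopulation, forces: dict[int, np.ndarray], params: CentreParameters
) -> None:
    """Overdamped forward Euler update, in place."""
    for i in pop.ids():
        f = forces[i]
        if not np.all(np.isfinite(f)):
            raise IntegrationError(f"non-finite force on cell {i}: {f}")
        pop.positions[i] = pop.positions[i] + (params.dt / params.drag) * f


def divide_centre_cell(
    pop: CentrePopulation,
    cell_id: int,
    cells: CellPopulation,
    cycle_params,
    params: CentreParameters,
    rng: np.random.Generator,
    t: float,
) -> tuple[int, int]:
    """Replace a division-ready cell by two daughters either side of it.

    Daughters sit at +-(newborn_separation/2) along a uniformly random
    direction about the parent position; the pair is registered for
    rest-length ramping.
    """
    parent = cells[cell_id]
    if not parent.cycle.ready:
        raise CellStateError(f"cell {cell_id} is not division-ready")
    centre = pop.positions[cell_id]
    theta = rng.uniform(0, 2 * np.pi)
    half = 0.5 * params.newborn_separation * np.array([np.cos(theta), np.sin(theta)])
    d1, d2 = make_daughters(parent, t, cells, cycle_params, rng)
    del pop.positions[cell_id]
    pop.positions[d1.id] = centre + half
    pop.positions[d2.id] = centre - half
    pop.sibling_since[frozenset((d1.id, d2.id))] = t
    return d1.id, d2.id
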