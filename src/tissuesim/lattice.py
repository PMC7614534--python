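"""On-lattice frameworks: cellular automaton (CA) and cellular Potts (CP).

CA: at most one cell per site; cells hop to vacant neighbour sites with a
configurable motility and place daughters in vacant neighbour sites.

CP: each cell is a set of sites evolving by Metropolis-accepted copy
attempts on the Hamiltonian

    H = sum_cells lambda_area * (A_s - A0_s)^2
      + sum_{neighbour site pairs} J(type_i, type_j) * [sigma_i != sigma_j]

with the adhesion matrix J indexed by cell-type pair plus a medium index
(last row/column).  Differential adhesion (J_AB exceeding the homotypic
mean) drives cell sorting, the lattice analogue of the vertex-model
showcase.

Copy proposals are restricted to heterogeneous neighbour pairs and the
energy change is evaluated locally over the flipped site's neighbourhood;
tests check this against a global recomputation.  Cell connectivity is NOT
enforced: domains can fragment at high temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cells import CellPopulation, CellStateError
from .geometry import Lattice

__all__ = [
    "PottsParameters",
    "CaParameters",
    "potts_energy",
    "delta_h",
    "metropolis_accept",
    "metropolis_attempt",
    "potts_step",
    "potts_divide",
    "ca_step",
    "heterotypic_interface_count",
]

log = logging.getLogger(__name__)

MEDIUM = -1  # adhesion-matrix index for empty sites


@dataclass
class PottsParameters:
    lambda_area: float = 1.0
    adhesion: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    temperature: float = 1.0
    sweeps_per_step: float = 1.0

    def __post_init__(self):
        self.adhesion = np.asarray(self.adhesion, dtype=float)
        if self.lambda_area < 0:
            raise ValueError("lambda_area must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not np.allclose(self.adhesion, self.adhesion.T):
            raise ValueError("adhesion matrix must be symmetric")


@dataclass
class CaParameters:
    motility: float = 1.0
    division_into_vacant: bool = True

    def __post_init__(self):
        if not (0 <= self.motility <= 1):
            raise ValueError("motility must lie in [0, 1]")


def _site_type(occ_value: int, cells: CellPopulation) -> int:
    if occ_value == 0:
        return MEDIUM
    if occ_value not in cells:
        raise CellStateError(f"occupancy references unknown cell {occ_value}")
    return cells[occ_value].type_label


def potts_energy(lattice: Lattice, cells: CellPopulation, params: PottsParameters) -> float:
    """Full Hamiltonian: area constraint plus interface adhesion.

    Each unordered neighbouring site pair is counted once; medium sites use
    the medium adhesion index and carry no area term.
    """
    h = 0.0
    for cid, area in lattice.cell_areas().items():
        if cid not in cells:
            raise CellStateError(f"occupancy references unknown cell {cid}")
        h += params.lambda_area * (area - cells[cid].target_area) ** 2
    occ = lattice.occupancy
    for x in range(lattice.width):
        for y in range(lattice.height):
            si = occ[x, y]
            ti = _site_type(si, cells)
            for dx, dy in lattice.offsets:
                # count each unordered pair once
                if not (dx > 0 or (dx == 0 and dy > 0)):
                    continue
                nx_, ny_ = x + dx, y + dy
                if not lattice.in_bounds(nx_, ny_):
                    continue
                sj = occ[nx_, ny_]
                if si != sj:
                    h += float(params.adhesion[ti, _site_type(sj, cells)])
    return h


def delta_h(
    lattice: Lattice,
    cells: CellPopulation,
    params: PottsParameters,
    source: tuple[int, int],
    target: tuple[int, int],
    areas: dict[int, int] | None = None,
) -> float:
    """Energy change of copying the source site's id onto the target site.

    Evaluated locally: adhesion terms over the target's neighbourhood plus
    the area terms of the two affected cells.  Identical to a global
    before/after recomputation of :func:`potts_energy`.
    """
    occ = lattice.occupancy
    s_new = int(occ[source])
    s_old = int(occ[target])
    if s_new == s_old:
        return 0.0
    if areas is None:
        areas = lattice.cell_areas()
    t_new = _site_type(s_new, cells)
    t_old = _site_type(s_old, cells)
    dh = 0.0
    if s_old != 0:
        a = areas[s_old]
        a0 = cells[s_old].target_area
        dh += params.lambda_area * ((a - 1 - a0) ** 2 - (a - a0) ** 2)
    if s_new != 0:
        a = areas.get(s_new, 0)
        a0 = cells[s_new].target_area
        dh += params.lambda_area * ((a + 1 - a0) ** 2 - (a - a0) ** 2)
    for nx_, ny_ in lattice.neighbours(*target):
        sk = int(occ[nx_, ny_])
        tk = _site_type(sk, cells)
        if sk != s_old:
            dh -= float(params.adhesion[t_old, tk])
        if sk != s_new:
            dh += float(params.adhesion[t_new, tk])
    return dh


def metropolis_accept(dh: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept with probability min(1, exp(-dH/T))."""
    if dh <= 0:
        return True
    return bool(rng.random() < np.exp(-dh / temperature))


def metropolis_attempt(
    lattice: Lattice,
    cells: CellPopulation,
    params: PottsParameters,
    rng: np.random.Generator,
    areas: dict[int, int] | None = None,
    proposal: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> bool:
    """One copy attempt: pick a random site and a random neighbour with a
    different id, propose copying the site's id onto the neighbour, accept by
    the Metropolis rule.  Returns whether the lattice changed.

    ``proposal`` fixes (source, target) for deterministic testing; ``areas``
    is the incremental area ledger maintained by :func:`potts_step` and is
    updated in place on acceptance.
    """
    if proposal is None:
        x = int(rng.integers(lattice.width))
        y = int(rng.integers(lattice.height))
        neigh = lattice.neighbours(x, y)
        source = (x, y)
        target = neigh[int(rng.integers(len(neigh)))]
    else:
        source, target = proposal
    occ = lattice.occupancy
    if occ[source] == occ[target]:
        return False
    dh = delta_h(lattice, cells, params, source, target, areas)
    if not metropolis_accept(dh, params.temperature, rng):
        return False
    s_new, s_old = int(occ[source]), int(occ[target])
    occ[target] = s_new
    if areas is not None:
        if s_old != 0:
            areas[s_old] -= 1
        if s_new != 0:
            areas[s_new] = areas.get(s_new, 0) + 1
    return True


def potts_step(
    lattice: Lattice,
    cells: CellPopulation,
    params: PottsParameters,
    rng: np.random.Generator,
) -> dict[int, int]:
    """One time step: ``sweeps_per_step * site count`` copy attempts.

    Cell areas are maintained incrementally (and equal a recount from the
    occupancy); cells reduced to zero sites are removed from the population.
    Returns the final area ledger.
    """
    areas = lattice.cell_areas()
    n_attempts = int(round(params.sweeps_per_step * lattice.width * lattice.height))
    for _ in range(n_attempts):
        metropolis_attempt(lattice, cells, params, rng, areas=areas)
    for cid in [cid for cid, a in areas.items() if a == 0]:
        del areas[cid]
        if cid in cells:
            cells.remove(cid)
            log.info("cell %d vanished (zero sites) and was removed", cid)
    return areas


def potts_divide(
    lattice: Lattice,
    cell_id: int,
    cells: CellPopulation,
    cycle_params,
    rng: np.random.Generator,
    t: float,
) -> tuple[int, int] | None:
    """Split a division-ready CP cell's sites across its long principal axis.

    Sites are ranked by projection onto the long axis of the site cloud and
    split at the median, giving daughters of as-equal-as-possible size.
    """
    from .cells import make_daughters

    sites = lattice.sites_of(cell_id)
    if len(sites) < 2:
        log.info("CP division of cell %d deferred: fewer than 2 sites", cell_id)
        return None
    pts = sites.astype(float)
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / len(pts)
    vals, vecs = np.linalg.eigh(cov)
    long_axis = vecs[:, -1]
    proj = d @ long_axis
    order = np.argsort(proj, kind="stable")
    half = len(sites) // 2
    parent = cells[cell_id]
    d1, d2 = make_daughters(parent, t, cells, cycle_params, rng)
    for idx in order[:half]:
        lattice.occupancy[tuple(sites[idx])] = d1.id
    for idx in order[half:]:
        lattice.occupancy[tuple(sites[idx])] = d2.id
    # daughters start with half the mature target area
    for dcell in (d1, d2):
        dcell.target_area = max(parent.target_area / 2.0, 1.0)
    return d1.id, d2.id


def ca_step(
    lattice: Lattice,
    cells: CellPopulation,
    params: CaParameters,
    rng: np.random.Generator,
    t: float,
    ready_ids: set[int] | None = None,
    cycle_params=None,
) -> None:
    """One cellular-automaton step with volume exclusion.

    Cells are visited in random order.  Each attempts, with probability
    ``motility``, a hop to a uniformly chosen vacant neighbour site (staying
    put if none is vacant).  Division-ready cells (``ready_ids``) then place
    a daughter in a uniformly chosen vacant neighbour, deferring if the
    neighbourhood is full.  Occupancy never exceeds one cell per site.
    """
    from .cells import make_daughters

    site_of: dict[int, tuple[int, int]] = {}
    for x, y in np.argwhere(lattice.occupancy != 0):
        site_of[int(lattice.occupancy[x, y])] = (int(x), int(y))
    ids = sorted(site_of)
    rng.shuffle(ids)
    for cid in ids:
        x, y = site_of[cid]
        if params.motility > 0 and rng.random() < params.motility:
            vacant = [s for s in lattice.neighbours(x, y) if lattice.occupancy[s] == 0]
            if vacant:
                new = vacant[int(rng.integers(len(vacant)))]
                lattice.occupancy[x, y] = 0
                lattice.occupancy[new] = cid
                site_of[cid] = new
    if ready_ids:
        from .cells import CycleParameters

        cyc = cycle_params if cycle_params is not None else CycleParameters()
        for cid in sorted(ready_ids):
            if cid not in site_of or cid not in cells:
                continue
            x, y = site_of[cid]
            vacant = [s for s in lattice.neighbours(x, y) if lattice.occupancy[s] == 0]
            if not vacant or not params.division_into_vacant:
                log.info("CA division of cell %d deferred: no vacant neighbour", cid)
                continue
            target = vacant[int(rng.integers(len(vacant)))]
            parent = cells[cid]
            d1, d2 = make_daughters(parent, t, cells, cyc, rng)
            lattice.occupancy[x, y] = d1.id
            lattice.occupancy[target] = d2.id
            del site_of[cid]
            site_of[d1.id] = (x, y)
            site_of[d2.id] = target


def heterotypic_interface_count(lattice: Lattice, cells: CellPopulation) -> int:
    """Number of neighbouring site pairs whose cells differ in type (both non-medium)."""
    occ = lattice.occupancy
    count = 0
    for x in range(lattice.width):
        for y in range(lattice.height):
            si = occ[x, y]
            if si == 0:
                continue
            for dx, dy in lattice.offsets:
                if not (dx > 0 or (dx == 0 and dy > 0)):
                    continue
                nx_, ny_ = x + dx, y + dy
                if not lattice.in_bounds(nx_, ny_):
                    continue
                sj = occ[nx_, ny_]
                if sj == 0 or sj == si:
                    continue
                if cells[si].type_label != cells[sj].type_label:
                    count += 1
    return count
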