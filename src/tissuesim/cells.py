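"""Biological cell state and the cell-cycle model hierarchy.

Three cycle-model kinds drive proliferation in every framework:

``fixed``
    deterministic phase durations; G1 is the midpoint of the configured
    uniform bounds so the same parameter block serves all kinds.
``uniform``
    G1 drawn once, at cell creation, from U(g1_min, g1_max); S, G2 and M
    are fixed.  Drawing at creation (not at query time) keeps replayed
    simulations bit-identical.
``contact_inhibited``
    like ``uniform`` but G1 progress pauses while the cell is compressed
    below a quiescent fraction of its target area; the total cycle duration
    extends by the arrested time.

A ``none`` kind is accepted everywhere and never divides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClockError",
    "CellStateError",
    "CycleParameters",
    "CellCycleState",
    "Cell",
    "CellPopulation",
    "advance_cycle",
    "make_daughters",
]

CYCLE_KINDS = ("none", "fixed", "uniform", "contact_inhibited")


class ClockError(ValueError):
    """A time step or time ordering precondition was violated."""


class CellStateError(RuntimeError):
    """An operation was applied to a cell in the wrong state."""


@dataclass
class CycleParameters:
    """Durations are in simulation time units (hours, conventionally)."""

    g1_min: float = 4.0
    g1_max: float = 6.0
    s: float = 4.0
    g2: float = 1.0
    m: float = 1.0
    quiescent_area_fraction: float = 0.8

    def __post_init__(self):
        if self.g1_min > self.g1_max:
            raise ValueError("g1_min must be <= g1_max")
        if min(self.g1_min, self.s, self.g2, self.m) < 0:
            raise ValueError("phase durations must be >= 0")
        if not (0 < self.quiescent_area_fraction <= 1):
            raise ValueError("quiescent_area_fraction must lie in (0, 1]")

    @property
    def sg2m(self) -> float:
        return self.s + self.g2 + self.m


@dataclass
class CellCycleState:
    model_kind: str = "none"
    g1: float = 0.0  # realised G1 duration (drawn for uniform kinds)
    progress: float = 0.0  # non-arrested time accumulated (contact_inhibited)
    arrested: bool = False
    ready: bool = False

    def total_duration(self, params: CycleParameters) -> float:
        return self.g1 + params.sg2m


def _draw_g1(kind: str, params: CycleParameters, rng: np.random.Generator) -> float:
    if kind == "fixed":
        return 0.5 * (params.g1_min + params.g1_max)
    if kind in ("uniform", "contact_inhibited"):
        return float(rng.uniform(params.g1_min, params.g1_max))
    return 0.0


def new_cycle_state(kind: str, params: CycleParameters, rng: np.random.Generator) -> CellCycleState:
    if kind not in CYCLE_KINDS:
        raise ValueError(f"unknown cycle model kind {kind!r}")
    return CellCycleState(model_kind=kind, g1=_draw_g1(kind, params, rng))


@dataclass
class Cell:
    id: int
    type_label: int = 0
    birth_time: float = 0.0
    target_area: float = 1.0
    cycle: CellCycleState = field(default_factory=CellCycleState)

    def __post_init__(self):
        if self.target_area <= 0:
            raise ValueError(f"cell {self.id}: target_area must be > 0")

    def age(self, t: float) -> float:
        if t < self.birth_time:
            raise ClockError(f"cell {self.id} queried before its birth time")
        return t - self.birth_time


class CellPopulation:
    """Live cells keyed by id, with a monotone id allocator."""

    def __init__(self, cells: list[Cell] | None = None):
        self.cells: dict[int, Cell] = {}
        self._next_id = 0
        for c in cells or []:
            self.add(c)

    def add(self, cell: Cell) -> None:
        if cell.id in self.cells:
            raise CellStateError(f"duplicate cell id {cell.id}")
        self.cells[cell.id] = cell
        self._next_id = max(self._next_id, cell.id + 1)

    def remove(self, cell_id: int) -> Cell:
        return self.cells.pop(cell_id)

    def allocate_id(self) -> int:
        nid = self._next_id
        self._next_id += 1
        return nid

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells.values())

    def __contains__(self, cell_id: int) -> bool:
        return cell_id in self.cells

    def __getitem__(self, cell_id: int) -> Cell:
        return self.cells[cell_id]

    def sorted_ids(self) -> list[int]:
        return sorted(self.cells)


def advance_cycle(
    cell: Cell,
    dt: float,
    t: float,
    current_area: float,
    params: CycleParameters,
    rng: np.random.Generator,
) -> bool:
    """Advance the cell's cycle over [t, t+dt]; return the division-ready flag.

    ``t`` is the time at the start of the step.  For the age-based kinds the
    flag depends only on age, so any partition of time into steps divides the
    cell at the same age (within one dt).  The contact-inhibited kind
    accumulates non-arrested time instead: while the current area is below
    ``quiescent_area_fraction * target_area`` during G1, progress pauses and
    the realised cycle duration extends accordingly.
    """
    if dt < 0:
        raise ClockError("negative dt")
    st = cell.cycle
    if st.model_kind == "none":
        return False
    if st.model_kind in ("fixed", "uniform"):
        st.arrested = False
        st.ready = cell.age(t) + dt >= st.total_duration(params)
        return st.ready
    if st.model_kind == "contact_inhibited":
        in_g1 = st.progress < st.g1
        st.arrested = in_g1 and current_area < params.quiescent_area_fraction * cell.target_area
        if not st.arrested:
            st.progress += dt
        st.ready = st.progress >= st.total_duration(params)
        return st.ready
    raise ValueError(f"unknown cycle model kind {st.model_kind!r}")


def make_daughters(
    parent: Cell,
    t: float,
    population: CellPopulation,
    params: CycleParameters,
    rng: np.random.Generator,
) -> tuple[Cell, Cell]:
    """Replace a division-ready parent with two newborn daughters.

    Daughters inherit ``type_label`` and ``target_area``, are born at ``t``
    with fresh ids, and (for the stochastic kinds) redraw G1 independently.
    The parent is removed from the population and the daughters added.
    """
    if not parent.cycle.ready:
        raise CellStateError(f"cell {parent.id} is not division-ready")
    if parent.id in population.cells:
        population.remove(parent.id)
    daughters = []
    for _ in range(2):
        d = Cell(
            id=population.allocate_id(),
            type_label=parent.type_label,
            birth_time=t,
            target_area=parent.target_area,
            cycle=new_cycle_state(parent.cycle.model_kind, params, rng),
        )
        population.add(d)
        daughters.append(d)
    return daughters[0], daughters[1]
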