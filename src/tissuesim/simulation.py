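"""The framework-agnostic simulation loop.

One step advances the clock by dt through a fixed phase order:

1. mechanics — nodal forces and overdamped Euler update (VM, PM, VT),
   Metropolis sweeps (CP), or motility moves (CA);
2. topological events — VM T1 swaps then T2 removals, in fixed id order;
3. cell-cycle advancement, then divisions in ascending cell-id order and
   removals;
4. modifiers, in declared order;
5. writers, whenever the step index falls on the sampling interval.

A single RNG stream (seeded from the scenario) is consumed in this fixed
phase order, so identical scenarios replay bit-identically.  Replay
stability when a phase is disabled is NOT guaranteed: removing a phase
shifts every later draw.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import centre as centre_mod
from . import lattice as lattice_mod
from . import vertex as vertex_mod
from .cells import Cell, CellPopulation, CycleParameters, advance_cycle, new_cycle_state
from .geometry import Lattice, VertexMesh, build_honeycomb_mesh, build_lattice_blob
from .scenario import Scenario
from .vtkio import SeriesIndex, write_frame, write_series_index

__all__ = [
    "SimulationState",
    "Modifier",
    "Writer",
    "TargetAreaGrowthModifier",
    "SortingMetricWriter",
    "EnergyWriter",
    "FrameWriter",
    "build_initial_state",
    "run",
]


@dataclass
class SimulationState:
    t: float
    structure: object  # VertexMesh | Lattice | CentrePopulation
    cells: CellPopulation
    rng: np.random.Generator
    framework: str
    scenario: Scenario

    def validate(self) -> None:
        """Cross-reference integrity: every structural unit maps to one live cell."""
        live = set(self.cells.cells)
        if isinstance(self.structure, VertexMesh):
            self.structure.validate()
            eids = set(self.structure.elements)
            if eids != live:
                raise AssertionError(f"element/cell mismatch: {eids ^ live}")
        elif isinstance(self.structure, Lattice):
            occ_ids = set(self.structure.cell_areas())
            if occ_ids != live:
                raise AssertionError(f"lattice/cell mismatch: {occ_ids ^ live}")
        else:
            nids = set(self.structure.positions)
            if nids != live:
                raise AssertionError(f"centre/cell mismatch: {nids ^ live}")


class Modifier:
    """Per-step hook that may mutate biological state (never break structure)."""

    def setup(self, state: SimulationState) -> None:  # pragma: no cover - trivial
        pass

    def update_at_end_of_step(self, state: SimulationState) -> None:
        raise NotImplementedError

    def finalize(self, state: SimulationState) -> None:  # pragma: no cover - trivial
        pass


class TargetAreaGrowthModifier(Modifier):
    """Ramp each cell's target area from half the mature value at birth to
    the mature value over ``growth_duration``."""

    def __init__(self, mature_area: float, growth_duration: float):
        self.mature_area = mature_area
        self.growth_duration = growth_duration

    def update_at_end_of_step(self, state: SimulationState) -> None:
        for cell in state.cells:
            age = state.t - cell.birth_time
            frac = min(age / self.growth_duration, 1.0) if self.growth_duration > 0 else 1.0
            cell.target_area = self.mature_area * (0.5 + 0.5 * frac)


class Writer:
    """Observation hook; must never mutate state."""

    def write(self, state: SimulationState, step_index: int) -> None:
        raise NotImplementedError

    def finalize(self, state: SimulationState) -> None:
        pass


class SeriesWriter(Writer):
    """Base for delimited text series: buffers rows, flushes per frame."""

    header = "t,value"
    filename = "series.csv"

    def __init__(self, out_dir: Path):
        self.path = Path(out_dir) / self.filename
        self.path.write_text(self.header + "\n")

    def append_row(self, *values) -> None:
        with open(self.path, "a") as fh:
            fh.write(",".join(str(v) for v in values) + "\n")


class SortingMetricWriter(SeriesWriter):
    """Time series of the heterotypic interface measure.

    VM: length fraction of interior edges between unlike cell types.
    CP: count of unlike-type neighbouring site pairs.
    Undefined metrics (no interfaces) record a NaN sentinel; the run continues.
    """

    header = "t,heterotypic"
    filename = "sorting_metric.csv"

    def write(self, state: SimulationState, step_index: int) -> None:
        if state.framework == "VM":
            try:
                value = vertex_mod.heterotypic_fraction(state.structure, state.cells)
            except vertex_mod.UndefinedMetricError:
                value = float("nan")
        elif state.framework == "CP":
            value = lattice_mod.heterotypic_interface_count(state.structure, state.cells)
        else:
            return
        self.append_row(state.t, value)


class EnergyWriter(SeriesWriter):
    """Tissue energy (VM) or Hamiltonian (CP) time series."""

    header = "t,energy"
    filename = "energy.csv"

    def write(self, state: SimulationState, step_index: int) -> None:
        if state.framework == "VM":
            value = vertex_mod.tissue_energy(
                state.structure, state.cells, state.scenario.vertex_parameters()
            )
        elif state.framework == "CP":
            value = lattice_mod.potts_energy(
                state.structure, state.cells, state.scenario.potts_parameters()
            )
        else:
            return
        self.append_row(state.t, value)


class FrameWriter(Writer):
    """VTU frame per sample plus the PVD collection index."""

    def __init__(self, out_dir: Path):
        self.out_dir = Path(out_dir)
        self.index = SeriesIndex()
        self.frame_count = 0

    def write(self, state: SimulationState, step_index: int) -> None:
        path = self.out_dir / f"frame_{self.frame_count:04d}.vtu"
        write_frame(state, path)
        self.index.append(state.t, path)
        self.frame_count += 1
        write_series_index(self.index, self.out_dir / "results.pvd")

    def finalize(self, state: SimulationState) -> None:
        if len(self.index):
            write_series_index(self.index, self.out_dir / "results.pvd")


# ---------------------------------------------------------------------------
# initial conditions


def _assign_types(n: int, rule, rng: np.random.Generator) -> list[int]:
    if rule.rule == "uniform":
        return [rule.type] * n
    if rule.rule == "random_two_type":
        return [int(rng.random() < rule.proportion) for _ in range(n)]
    # half_and_half: first half type 0, second half type 1, in id order
    return [0 if k < (n + 1) // 2 else 1 for k in range(n)]


def build_initial_state(scenario: Scenario, rng: np.random.Generator | None = None) -> SimulationState:
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    geo = scenario.geometry
    cyc = scenario.cycle_parameters()
    cells = CellPopulation()

    def make_cell(cid: int, type_label: int, target_area: float) -> Cell:
        return Cell(
            id=cid,
            type_label=type_label,
            birth_time=0.0,
            target_area=target_area,
            cycle=new_cycle_state(scenario.cycle.model, cyc, rng),
        )

    fw = scenario.framework
    if fw == "VM":
        if geo.generator != "honeycomb":
            raise ValueError("VM scenarios use the honeycomb generator")
        mesh = build_honeycomb_mesh(geo.nx, geo.ny, geo.edge)
        types = _assign_types(len(mesh.elements), scenario.cell_types, rng)
        for eid in sorted(mesh.elements):
            cells.add(make_cell(eid, types[eid], mesh.element_area(eid)))
        structure = mesh
    elif fw in ("CA", "CP"):
        if geo.generator != "lattice_blob":
            raise ValueError(f"{fw} scenarios use the lattice_blob generator")
        order = scenario.ca.neighbourhood_order if fw == "CA" else scenario.potts.neighbourhood_order
        lattice = build_lattice_blob(
            geo.width, geo.height, geo.radius, geo.n_cells, fw, rng, neighbourhood_order=order
        )
        areas = lattice.cell_areas()
        types = _assign_types(len(areas), scenario.cell_types, rng)
        for k, cid in enumerate(sorted(areas)):
            if fw == "CP":
                a0 = scenario.potts.target_area
            else:
                a0 = 1.0
            cells.add(make_cell(cid, types[k], a0))
        structure = lattice
    else:  # PM / VT
        if geo.generator != "point_grid":
            raise ValueError("centre-model scenarios use the point_grid generator")
        positions = {}
        cid = 0
        for row in range(geo.ny):
            for col in range(geo.nx):
                jitter = geo.jitter * rng.uniform(-1, 1, size=2)
                positions[cid] = np.array([col, row], dtype=float) + jitter
                cid += 1
        mode = "overlapping_spheres" if fw == "PM" else "voronoi"
        structure = centre_mod.CentrePopulation(positions, connectivity_mode=mode)
        types = _assign_types(len(positions), scenario.cell_types, rng)
        for k in sorted(positions):
            cells.add(make_cell(k, types[k], 1.0))
    return SimulationState(
        t=0.0, structure=structure, cells=cells, rng=rng, framework=fw, scenario=scenario
    )


# ---------------------------------------------------------------------------
# per-framework step phases


def _current_area(state: SimulationState, cell_id: int, areas=None) -> float:
    if state.framework == "VM":
        return state.structure.element_area(cell_id)
    if state.framework == "CP":
        if areas is not None:
            return float(areas.get(cell_id, 0))
        return float(len(state.structure.sites_of(cell_id)))
    return 1.0  # CA / centre models: unit footprint convention


def _step_vm(state: SimulationState, params, cyc: CycleParameters) -> None:
    mesh: VertexMesh = state.structure
    # phase 1: mechanics (noise drawn in fixed node order, then forces)
    if params.noise > 0:
        for nid in sorted(mesh.nodes):
            mesh.nodes[nid].position = mesh.nodes[nid].position + params.noise * state.rng.standard_normal(2)
    forces = vertex_mod.nodal_forces(mesh, state.cells, params)
    scale = params.dt / params.drag
    for nid in sorted(mesh.nodes):
        mesh.nodes[nid].position = mesh.nodes[nid].position + scale * forces[nid]
    # phase 2: T1 swaps then T2 removals, fixed id order, one pass each
    for edge in vertex_mod.find_t1_edges(mesh, params):
        vertex_mod.t1_swap(mesh, edge, params)
    for eid in vertex_mod.find_t2_elements(mesh, params):
        if eid in mesh.elements:
            vertex_mod.t2_remove(mesh, eid, state.cells, params)
    # phase 3: cycles and divisions
    ready = _advance_cycles(state, cyc)
    for cid in ready:
        if cid in mesh.elements:
            vertex_mod.divide_element(mesh, cid, state.cells, cyc, state.rng, state.t + params.dt)


def _step_cp(state: SimulationState, params, cyc: CycleParameters) -> None:
    areas = lattice_mod.potts_step(state.structure, state.cells, params, state.rng)
    ready = _advance_cycles(state, cyc, areas=areas)
    for cid in ready:
        if cid in state.cells:
            lattice_mod.potts_divide(
                state.structure, cid, state.cells, cyc, state.rng, state.t + state.scenario.clock.dt
            )


def _step_ca(state: SimulationState, params, cyc: CycleParameters) -> None:
    ready = set(_advance_cycles(state, cyc))
    lattice_mod.ca_step(
        state.structure,
        state.cells,
        params,
        state.rng,
        state.t + state.scenario.clock.dt,
        ready_ids=ready,
        cycle_params=cyc,
    )


def _step_centre(state: SimulationState, params, cyc: CycleParameters) -> None:
    pop = state.structure
    pairs = centre_mod.neighbour_pairs(pop, params)
    forces = centre_mod.spring_forces(pop, pairs, state.cells, params, state.t, rng=state.rng)
    centre_mod.step_positions(pop, forces, params)
    ready = _advance_cycles(state, cyc)
    for cid in ready:
        if cid in pop.positions:
            centre_mod.divide_centre_cell(
                pop, cid, state.cells, cyc, params, state.rng, state.t + params.dt
            )


def _advance_cycles(state: SimulationState, cyc: CycleParameters, areas=None) -> list[int]:
    """Advance every live cell's cycle over this step; ready ids, ascending."""
    dt = state.scenario.clock.dt
    ready = []
    for cid in state.cells.sorted_ids():
        cell = state.cells[cid]
        if advance_cycle(cell, dt, state.t, _current_area(state, cid, areas), cyc, state.rng):
            ready.append(cid)
    return ready


_STEPPERS = {"VM": _step_vm, "CP": _step_cp, "CA": _step_ca, "PM": _step_centre, "VT": _step_centre}


def _framework_params(scenario: Scenario):
    return {
        "VM": scenario.vertex_parameters,
        "CP": scenario.potts_parameters,
        "CA": scenario.ca_parameters,
        "PM": scenario.centre_parameters,
        "VT": scenario.centre_parameters,
    }[scenario.framework]()


def _build_modifiers(scenario: Scenario) -> list[Modifier]:
    out = []
    for cfg in scenario.modifiers:
        if cfg.name == "target_area_growth":
            out.append(TargetAreaGrowthModifier(cfg.mature_area, cfg.growth_duration))
    return out


def run(
    scenario: Scenario,
    output_dir: str | Path | None = None,
    check_invariants: bool = False,
    extra_writers: list[Writer] | None = None,
) -> SimulationState:
    """Run a scenario to completion, writing frames, series and a manifest.

    ``check_invariants`` re-validates all structural invariants and
    cross-references after every step (test mode); violations abort with the
    step index.  Returns the final state.
    """
    out_dir = Path(output_dir) if output_dir is not None else Path(scenario.output_dir or "out")
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    state = build_initial_state(scenario, rng)
    params = _framework_params(scenario)
    cyc = scenario.cycle_parameters()
    modifiers = _build_modifiers(scenario)
    writers: list[Writer] = [FrameWriter(out_dir)]
    if scenario.framework in ("VM", "CP"):
        writers.append(SortingMetricWriter(out_dir))
        writers.append(EnergyWriter(out_dir))
    writers.extend(extra_writers or [])

    clock = scenario.clock
    n_steps = int(round(clock.end_time / clock.dt))
    sample_every = int(round(clock.sampling_interval / clock.dt))
    for m in modifiers:
        m.setup(state)
    for w in writers:
        w.write(state, 0)
    stepper = _STEPPERS[scenario.framework]
    for step in range(1, n_steps + 1):
        stepper(state, params, cyc)
        state.t = step * clock.dt
        for m in modifiers:
            m.update_at_end_of_step(state)
        if check_invariants:
            try:
                state.validate()
            except Exception as exc:
                raise AssertionError(f"invariant violation at step {step}: {exc}") from exc
        if step % sample_every == 0:
            for w in writers:
                w.write(state, step)
    for m in modifiers:
        m.finalize(state)
    for w in writers:
        w.finalize(state)
    manifest = {
        "final_time": state.t,
        "cell_count": len(state.cells),
        "seed": scenario.seed,
        "framework": scenario.framework,
        "steps": n_steps,
        "scenario": scenario.model_dump(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return state


def hash_outputs(out_dir: str | Path) -> str:
    """SHA-256 over all frame files and series, for replay-determinism checks."""
    out_dir = Path(out_dir)
    digest = hashlib.sha256()
    for path in sorted(out_dir.glob("*")):
        if path.suffix in (".vtu", ".pvd", ".csv"):
            digest.update(path.name.encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()
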