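"""Declarative scenario configuration.

A Scenario is the full description of one simulation: framework choice,
initial geometry, mechanical parameters, cell-cycle model, cell-type
assignment, clock, RNG seed and output settings.  Scenarios are plain JSON;
validation (pydantic) rejects unknown keys and reports every violation at
once, and a parsed scenario serialises back to an equal scenario, so runs
are fully self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = ["Scenario", "ScenarioError", "parse_scenario", "scenario_from_dict"]

Framework = Literal["CA", "CP", "PM", "VT", "VM"]


class ScenarioError(ValueError):
    """Scenario validation failed; the message lists every violation."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySpec(_Block):
    generator: Literal["honeycomb", "lattice_blob", "point_grid"]
    # honeycomb
    nx: int = 4
    ny: int = 4
    edge: float = 1.0
    # lattice_blob
    width: int = 30
    height: int = 30
    radius: float = 10.0
    n_cells: int = 20
    # point_grid (centre models): nx * ny points at unit spacing plus jitter
    jitter: float = 0.05


class VertexBlock(_Block):
    k_area: float = 1.0
    k_perimeter: float = 0.02
    gamma_homotypic: float = 0.01
    gamma_heterotypic: float = 0.01
    gamma_medium: float = 0.05
    d_t1: float = 0.1
    t1_separation_ratio: float = 1.5
    a_t2: float = 0.1
    drag: float = 1.0
    noise: float = 0.0


class PottsBlock(_Block):
    lambda_area: float = 1.0
    j_homotypic: float = 2.0
    j_heterotypic: float = 11.0
    j_medium: float = 16.0
    temperature: float = 10.0
    sweeps_per_step: float = 1.0
    target_area: float = 16.0
    neighbourhood_order: Literal["von_neumann", "moore"] = "moore"


class CaBlock(_Block):
    motility: float = 1.0
    division_into_vacant: bool = True
    neighbourhood_order: Literal["von_neumann", "moore"] = "von_neumann"


class CentreBlock(_Block):
    stiffness: float = 15.0
    rest_length: float = 1.0
    growth_duration: float = 1.0
    newborn_separation: float = 0.3
    drag: float = 1.0
    cutoff: float = 1.5


class CycleBlock(_Block):
    model: Literal["none", "fixed", "uniform", "contact_inhibited"] = "none"
    g1_min: float = 4.0
    g1_max: float = 6.0
    s: float = 4.0
    g2: float = 1.0
    m: float = 1.0
    quiescent_area_fraction: float = 0.8


class TypeRule(_Block):
    rule: Literal["uniform", "random_two_type", "half_and_half"] = "uniform"
    type: int = 0  # uniform rule
    proportion: float = 0.5  # P(type 1) under random_two_type


class ClockBlock(_Block):
    dt: float = 0.01
    end_time: float = 1.0
    sampling_interval: float = 0.1

    @model_validator(mode="after")
    def _check(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.end_time < 0:
            raise ValueError("end_time must be >= 0")
        ratio = self.sampling_interval / self.dt
        if self.sampling_interval <= 0 or abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("sampling_interval must be a positive multiple of dt")
        return self


class ModifierConfig(_Block):
    name: Literal["target_area_growth"]
    mature_area: float = 1.0
    growth_duration: float = 1.0


class Scenario(_Block):
    framework: Framework
    geometry: GeometrySpec
    vertex: VertexBlock | None = None
    potts: PottsBlock | None = None
    ca: CaBlock | None = None
    centre: CentreBlock | None = None
    cycle: CycleBlock = Field(default_factory=CycleBlock)
    cell_types: TypeRule = Field(default_factory=TypeRule)
    clock: ClockBlock = Field(default_factory=ClockBlock)
    seed: int = 0
    output_dir: str | None = None
    modifiers: list[ModifierConfig] = Field(default_factory=list)

    @model_validator(mode="after")
    def _one_matching_block(self):
        needed = {"VM": "vertex", "CP": "potts", "CA": "ca", "PM": "centre", "VT": "centre"}[
            self.framework
        ]
        present = {
            name
            for name in ("vertex", "potts", "ca", "centre")
            if getattr(self, name) is not None
        }
        if present - {needed}:
            raise ValueError(
                f"framework {self.framework} takes only the {needed!r} parameter block; "
                f"found {sorted(present)}"
            )
        if needed not in present:
            # fill the matching block with defaults so runs are self-describing
            defaults = {"vertex": VertexBlock, "potts": PottsBlock, "ca": CaBlock, "centre": CentreBlock}
            setattr(self, needed, defaults[needed]())
        return self

    # -- conversion to runtime parameter objects ---------------------------

    def vertex_parameters(self):
        from .vertex import VertexParameters

        b = self.vertex
        n_types = 2
        gamma = np.full((n_types + 1, n_types + 1), b.gamma_heterotypic)
        np.fill_diagonal(gamma, b.gamma_homotypic)
        gamma[-1, :] = gamma[:, -1] = b.gamma_medium
        gamma[-1, -1] = 0.0
        return VertexParameters(
            k_area=b.k_area,
            k_perimeter=b.k_perimeter,
            gamma=gamma,
            d_t1=b.d_t1,
            t1_separation_ratio=b.t1_separation_ratio,
            a_t2=b.a_t2,
            drag=b.drag,
            dt=self.clock.dt,
            noise=b.noise,
        )

    def potts_parameters(self):
        from .lattice import PottsParameters

        b = self.potts
        n_types = 2
        adhesion = np.full((n_types + 1, n_types + 1), b.j_heterotypic)
        np.fill_diagonal(adhesion, b.j_homotypic)
        adhesion[-1, :] = adhesion[:, -1] = b.j_medium
        adhesion[-1, -1] = 0.0
        return PottsParameters(
            lambda_area=b.lambda_area,
            adhesion=adhesion,
            temperature=b.temperature,
            sweeps_per_step=b.sweeps_per_step,
        )

    def ca_parameters(self):
        from .lattice import CaParameters

        return CaParameters(
            motility=self.ca.motility, division_into_vacant=self.ca.division_into_vacant
        )

    def centre_parameters(self):
        from .centre import CentreParameters

        b = self.centre
        return CentreParameters(
            stiffness=b.stiffness,
            rest_length=b.rest_length,
            growth_duration=b.growth_duration,
            newborn_separation=b.newborn_separation,
            drag=b.drag,
            dt=self.clock.dt,
            cutoff=b.cutoff,
        )

    def cycle_parameters(self):
        from .cells import CycleParameters

        c = self.cycle
        return CycleParameters(
            g1_min=c.g1_min,
            g1_max=c.g1_max,
            s=c.s,
            g2=c.g2,
            m=c.m,
            quiescent_area_fraction=c.quiescent_area_fraction,
        )

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)


def scenario_from_dict(data: dict) -> Scenario:
    try:
        return Scenario.model_validate(data)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ScenarioError("invalid scenario:\n  " + "\n  ".join(lines)) from exc


def parse_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario JSON file."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ScenarioError(f"{path}: not valid JSON ({exc})") from exc
    return scenario_from_dict(data)
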