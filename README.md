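# tissuesim

A 2-D multi-framework cell-based tissue simulator. Developmental and cancer
biology use several discrete descriptions of the same tissue — and which one
you pick changes what you can ask. `tissuesim` implements five of them
behind a single simulation loop so they can be compared like for like:

- **CA** — cellular automaton: one cell per lattice site, exclusion moves;
- **CP** — cellular Potts: cells as site domains, Metropolis dynamics on
  H = Σ λ(A−A0)² + Σ J(τ_i,τ_j)[σ_i≠σ_j];
- **PM** — cell-centre, overlapping spheres: point cells, linear springs
  F = μ(|r|−s)r̂ between centres within a cutoff;
- **VT** — cell-centre, Voronoi tessellation: spring neighbours from
  Delaunay edges, Voronoi polygons as cell shapes;
- **VM** — vertex model: cells as polygons with shared edges, vertices
  descending U = Σ k_A/2 (A−A0)² + Σ k_P/2 P² + Σ γ(τ_l,τ_r) ℓ, with T1/T2
  rearrangements.

All five share cell-cycle models (fixed, uniform-G1, contact-inhibited),
modifier and writer hooks, deterministic seeded runs, and VTK time-series
output (ParaView-ready `results.pvd` + VTU frames, colourable by the
"Cell types" array). Scenarios are declarative JSON. The flagship
demonstration is differential-adhesion cell sorting: make heterotypic
interfaces costlier than homotypic ones (γ_AB > (γ_AA+γ_BB)/2, or
J_AB > (J_AA+J_BB)/2) and a randomly mixed two-type tissue unmixes.

## Worked example

Run the vertex-model cell-sorting showcase:

```
tissuesim demo sorting --seed 1 --out sorting_out
```

This relaxes a 6×6 honeycomb of 36 cells, half of each type, for 30 hours
of simulated time with heterotypic line tension 0.2 against homotypic 0.02,
writing a frame every hour. `sorting_out/` then contains `results.pvd`,
31 VTU frames, `sorting_metric.csv`, `energy.csv` and `manifest.json`.
The metric series tracks the length fraction of cell–cell interface shared
by unlike types:

```
$ head -2 sorting_out/sorting_metric.csv; tail -1 sorting_out/sorting_metric.csv
t,heterotypic
0.0,0.5411764705882353
30.0,0.4329496635959803
```

A random half/half mixture starts near 0.5; the decline to ≈0.43 is the
sorting signal (perfect sorting into two compact blocks would approach
≈0.1, but finite tissues at finite noise arrest well above that). Open
`results.pvd` in ParaView and colour by "Cell types" to watch the domains
coarsen. `tissuesim demo potts-sort` is the lattice analogue;
`tissuesim run scenario.json [--seed N] [--out DIR]` and
`tissuesim validate scenario.json` run and check your own scenarios.

The same machinery is available as a library:

```python
from tissuesim.cli import demo_scenario
from tissuesim.simulation import run

state = run(demo_scenario("sorting", seed=1), output_dir="sorting_out")
print(len(state.cells))   # 36
```

## Layout

| module | contents |
| --- | --- |
| `tissuesim.geometry` | polygon measures, Delaunay/Voronoi, honeycomb and lattice-blob generators, `VertexMesh`/`Lattice` containers |
| `tissuesim.cells` | `Cell`, cycle models, division bookkeeping |
| `tissuesim.vertex` | VM energy, analytic forces, T1/T2, element division, sorting metric |
| `tissuesim.lattice` | CP Hamiltonian and Metropolis sweeps, CA exclusion dynamics |
| `tissuesim.centre` | PM/VT neighbour graphs, spring forces, overdamped updates |
| `tissuesim.simulation` | the shared loop, modifiers, writers, manifests |
| `tissuesim.scenario` / `tissuesim.vtkio` / `tissuesim.cli` | JSON scenarios, VTU/PVD output, command line |

See `docs/methods.md` for model details, parameter defaults, numerical
choices and known limitations.
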