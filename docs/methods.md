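# Methods

`tissuesim` implements five interchangeable 2-D representations of a
multicellular tissue behind one simulation loop. This note records the
models, their assumptions, the default parameters and the numerical choices,
so results can be interpreted (and distrusted) correctly.

All lengths are dimensionless with one typical cell diameter as the unit;
time is in hours by convention. Ids are 0-based; lattice cell id 0 is
reserved for the medium.

## Frameworks

### Vertex model (VM)

Each cell is a counter-clockwise polygon sharing edges and vertices with its
neighbours. The tissue energy is

    U = Σ_i k_A/2 (A_i − A0_i)² + Σ_i k_P/2 P_i² + Σ_edges γ(τ_l, τ_r) ℓ_e

with area elasticity `k_area` (default 1.0), perimeter contractility
`k_perimeter` (default 0.02), and a symmetric line-tension matrix γ indexed
by the two flanking cell types; boundary edges use an extra "medium" index.
There is no target perimeter: a P0 term is absorbable into the line tension,
and keeping the pure-contractility form makes the typed tension the single
knob for differential adhesion. Vertices move by overdamped forward Euler,
x ← x + (dt/η)·(−∂U/∂x), with analytic gradients (the area gradient at a
vertex is half the 90°-rotated vector between its ring neighbours).

Topological maintenance per step, in fixed ascending id order: T1 swaps on
interior edges strictly shorter than `d_t1` (default 0.1), repositioning the
two nodes perpendicular to the old edge at separation
`t1_separation_ratio × d_t1` (default ratio 1.5), at most one swap per edge
per step; then T2 removal of triangular elements with area below `a_t2`
(default 0.1), replacing the triangle by a node at its centroid. Division
splits an element through its centroid along the shortest principal axis of
its vertex cloud (so cells divide across their elongation); the two boundary
intersection nodes are also inserted into the neighbouring elements to
preserve edge sharing. A cut that does not cross exactly two edges defers
the division by one step.

Stability: for k_area = 1, drag = 1 and cells of area ≈ 2.6, dt = 0.01 is
the documented bound at which quasi-static relaxation is monotone in energy;
larger steps can overshoot. Boundary (T3) collisions are not handled, so
scenarios keep tissues simply connected.

Sorting scenarios add a small isotropic Gaussian displacement per node per
step (`noise`, default 0; the bundled showcase uses 0.012). This is the
explicit, configured stand-in for active fluctuations; without it a tissue
sits in the nearest local minimum and sorting stalls.

### Cellular Potts model (CP)

Cells are sets of lattice sites; the Hamiltonian is

    H = Σ_s λ (A_s − A0_s)² + Σ_<ij> J(τ_i, τ_j) [σ_i ≠ σ_j]

with each unordered neighbouring site pair counted once (Moore neighbourhood
by default for the interface term — von Neumann over-rewards axis-aligned
interfaces). One time step performs `sweeps_per_step × site-count` copy
attempts: pick a random site and random neighbour with a different id,
propose copying the id onto the neighbour, accept with probability
min(1, e^(−ΔH/T)). ΔH is evaluated locally over the flipped site's
neighbourhood and is identity-tested against global recomputation. Cell
areas are maintained incrementally; cells at zero sites are removed.
Connectivity is NOT enforced: domains can fragment at high temperature, and
this is accepted rather than patched with a connectivity constraint.
Division (when a cycle model is attached) splits the cell's sites at the
median of their projection onto the long principal axis — a convention of
this package, chosen to give equal-size daughters.

The sorting showcase uses the classic strong-heterotypic regime
J_AA = J_BB = 2, J_AB = 11, J_cell,medium = 16, λ = 1, T = 10, ~16 sites per
cell.

### Cellular automaton (CA)

At most one cell per site (volume exclusion), von Neumann neighbourhood by
default. Per step, cells are visited in random order; each attempts with
probability `motility` a hop to a uniformly chosen vacant neighbour (staying
if none), and division-ready cells then place one daughter in a uniformly
chosen vacant neighbour, deferring while crowded. A lone walker at
motility 1 therefore performs an unbiased random walk with MSD of one
site² per step.

### Cell-centre models (PM, VT)

Each cell is a point; neighbour pairs interact through a linear spring
F = μ(|r| − s) r̂, attractive beyond the rest length s (default 1) and
repulsive inside it, with μ = 15 by default. Neighbours come either from a
distance cutoff (overlapping spheres, default 1.5) or from Delaunay edges of
the centres (the Voronoi-tessellation view; Delaunay edges are unrestricted,
so boundary cells can acquire distant spurious neighbours — a documented
limitation of that mode). After division the sibling pair's rest length
ramps linearly from `newborn_separation` (0.3) to s over `growth_duration`
(1.0), after which the pair is forgotten. Two isolated cells at separation
s + δ0 relax as s + δ0·e^(−2μt/η), used as a closed-form integrator check.

## Cell cycle

Three cycle kinds share one parameter block (G1 bounds, fixed S/G2/M
durations, a quiescent area fraction): `fixed` (G1 = midpoint of the
bounds), `uniform` (G1 ~ U(g1_min, g1_max), drawn once at cell creation for
replay stability), and `contact_inhibited` (uniform, but G1 progress pauses
while the cell's current area is below `quiescent_area_fraction ×
target_area`, extending the realised cycle by the arrested time). A `none`
kind never divides. Daughters inherit type and target area and redraw G1
independently. For CA and the centre models the "current area" fed to
contact inhibition is the unit footprint, so that kind is only meaningfully
inhibitory for VM and CP.

## Simulation loop and reproducibility

Per step: mechanics → (VM) T1 then T2 → cycle advancement → divisions in
ascending cell-id order → modifiers in declared order → writers on sampling
steps. For CA, cycle advancement precedes the combined move/division sweep
so the step is one lattice pass. A single `numpy` Generator seeded from the
scenario is consumed in this fixed order, making same-seed runs
byte-identical; disabling any phase shifts all later draws, so replay
stability across *different* scenarios is explicitly not promised. In test
mode every structural invariant (edge sharing, positive areas, node
separation, structure/cell cross-references) is re-checked after every step.

The `target_area_growth` modifier ramps each cell's target area from half
the mature value at birth to the mature value over a growth duration —
the reference modifier implementation.

## Output

Frames are XML VTU files with plain inline ASCII arrays (no binary
blocks), 2-D points embedded with z = 0, indexed by a PVD collection file;
the integer cell-data array is named exactly "Cell types" so ParaView users
can colour by type. VM frames export one polygon per cell, VT frames the
box-clipped Voronoi polygon of each centre, PM frames one vertex glyph per
centre, and CA/CP frames one unit quad per occupied site. Metric series
(tissue energy, heterotypic interface measure) are CSV with a header row;
NaN marks an undefined metric (e.g. a single-cell tissue has no interior
interfaces). Every run writes a manifest echoing the fully resolved
scenario, final time, cell count and seed.

## What the bundled scenarios do and do not show

The generators produce idealised initial conditions: perfect honeycombs,
disc-shaped lattice blobs (CP blobs partitioned by balanced multi-source
BFS into 4-connected domains), jittered point grids. Passing tests
demonstrate internal consistency — forces equal energy gradients, Metropolis
acceptance follows the Boltzmann factor, sorting emerges from differential
adhesion, runs replay exactly — on tissues of tens of cells over tens of
hours. They do not calibrate any parameter against experimental tissue;
parameter defaults are chosen for numerical robustness, not biological
fidelity, and 3-D effects, periodic boundaries, subcellular reaction
networks and boundary (T3) topology are out of scope.

Problem sizes used by the verification script: 22 random configurations for
the gradient oracle, 500 relaxation steps, 9 × 10⁵ Metropolis trials,
50 tessellation point sets, 10³ random-walk replicates, and 5 seeds × 36
cells (VM) / 12 cells (CP) for the sorting showcase.
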