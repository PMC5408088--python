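# Methods

`vascufab` simulates a two-dimensional "vascular cell factory": a culture in
which bioengineered endothelial-like cells self-organize into a perfusable
vessel network that feeds product-synthesizing microbial cells and carries
their product away. The simulation has three phases — morphogenesis, pipe
network extraction with a laminar-flow solve, and steady-state factory
operation — followed by an evaluation harness (fraction sweep, seed
robustness, width scaling).

Internal units are micrometres, seconds, picograms and pascals throughout;
diffusion coefficients are given in m²/s at the configuration boundary and
converted once (1 m²/s = 10¹² μm²/s). Concentrations are areal densities
(pg/μm²) on the shared 2D grid; the grid is row-major with row 0 at the
bottom, pixel centres at ((j+½)h, (i+½)h), and zero-flux borders on all four
edges (a closed culture).

## Geometry and initial state

The domain is a W × H rectangle (reference scale 1028 × 516 μm; desk scale
258 × 258 μm). Two immobile circulatory columns hug the vertical edges —
source on the left, sink on the right — each holding half of
`n_circulatory` cells evenly spaced over the full height, emulating the
external supply and extraction circuit. `n_interior_cells` particles are
seeded uniformly at random strictly between the columns; each is vascular
with probability `vascular_fraction`, otherwise a producer.

All cells are disks of radius 2.3 μm on a 1 μm/pixel grid. This radius is a
deliberate design choice: with the stated cell counts (24,000 at reference
scale, 3000 at desk scale) it puts both geometries at the same ~75% area
coverage — a crowded monolayer, which matters because crowding is one of
the ingredients of cord formation — while remaining below the close-packing
bound (≈ 90.7%), which `make_initial_state` enforces. Initial overlaps are
left to the shoving relaxation.

## Phase I — morphogenesis

Two chemoattractant species diffuse with D_c = 10⁻¹³ m²/s and differ only in
decay rate: the species secreted by vascular cells decays fast
(β_v = 0.1/144 s⁻¹, decay length √(D_c/β_v) ≈ 12 μm) and the species
secreted by the circulatory columns decays slowly (β_c = 2×10⁻⁵ s⁻¹, range
≈ 70 μm). Secretion follows Monod kinetics in a non-depleting substrate,
rate μ_c·N_c/(N_c+k)·M per cell, deposited over the pixels the cell covers.
The vascular field is advanced by an explicit 5-point forward-Euler stepper
(decay applied as an exact exponential factor, so positivity needs no
clamping; the time step respects h²/4D) and re-relaxed by a fixed number of
substeps per mechanical step as its sources move. The circulatory field's
sources never move, so it is computed once as the exact stationary point of
the same stencil (one sparse linear solve) instead of being time-stepped to
its slow equilibrium.

Each mechanical step, every vascular cell samples `n_directions = 6` random
unit vectors; for each, the summed field (vascular field plus
`lambda_long_ratio = 0.1` times the circulatory field) is read one radius
ahead (C⁺) and behind (C⁻) by bilinear interpolation, and the saturating
response F = λ[C⁺/(1+βC⁺) − C⁻/(1+βC⁻)] is applied along the direction only
when positive. Two regimes of this law matter:

* **Unsaturated (βC ≪ 1):** F ≈ λ(C⁺−C⁻). Plain gradient drift. Round
  particles under this law collapse into isolated islands (the classic
  outcome for overdamped chemotaxis without cell elongation), which never
  percolate.
* **Deeply saturated (βC ≫ 1):** F ≈ (λ/β)·Δ(−1/(βC)), i.e. the response is
  normalized by the local concentration — effectively logarithmic sensing.
  Cords then still attract each other across low-concentration lanes, and
  a cell at a cord tip is not recaptured by its own cord's much louder
  field. The defaults λ = 2000, β_sat = 50 put the working point deep in
  this regime (typical cord-surface concentrations give βC ≈ 5–25).

Chemotaxis is **contact-inhibited**: a sampled direction pointing into a
touching vascular neighbour (within `contact_margin` = 0.5 μm surface gap,
inside a cone of half-angle 60°) produces no force, while tangential sliding
along a neighbour stays allowed. This is the particle analogue of
contact-inhibited protrusion in endothelial collectives and is the second
ingredient that stabilizes cords: without it, aggregates compact into round
islands; with it, protrusive activity is confined to free surface and
aggregates extend. The third ingredient is short-range homotypic adhesion
(linear ramp over a 2 μm surface gap, strength 0.3), which locks formed
cords together.

Forces convert to displacement by overdamped motion Δx = mobility·F·Δt,
capped at one cell radius per step; overlaps are then resolved by an
iterative shoving relaxation (each overlapping pair separates by half the
overlap along its axis; a pair with an immobile circulatory partner puts
the whole correction on the mobile cell; coincident centres split along a
direction hashed from the cell ids, keeping runs deterministic). Cells are
processed in id order and all randomness flows from one generator, so a
(config, seed) pair reproduces the morphology bit for bit.

The loop stops when the largest displacement and the relative field change
stay below thresholds for `patience` consecutive steps, or at `max_steps`.
With stochastic protrusion sampling the displacement criterion essentially
never fires, so `max_steps` is the effective morphogenesis duration, and it
is a real model parameter: the cord web forms within ~150–250 steps at the
desk scale and *coarsening beyond that point disconnects it again* (cords
thicken, lanes widen). The desk-scale default is 300 steps; the calibration
freeze is described below.

### What the emergent behaviour reproduces

With the frozen defaults the desk-scale model reproduces the reference
narrative of connectivity versus vascular fraction: at ≤ 15% only isolated
fragments form (0/5 seeds connected); at 20–25% connection is rare
(1/5 and 2/5); from 30% upward every seed forms a source-to-sink connected
network. Above ~60% the vascular phase is a majority and merges into broad
slabs with small producer lacunae.

## Phase II — pipe network extraction and flow

The vascular cells are rasterized as filled disks fattened by
`mask_dilation` = 1.25 μm (the in-memory replacement for rendering cells as
illuminated spheres before thresholding), followed by two passes of 3×3
binary closing that bridge sub-pixel gaps between touching cells. Local
vessel width is twice the Euclidean distance transform (a true
largest-inscribed-disk thickness is available as an option), and the mask
is thinned to a one-pixel, 8-connected, topology-preserving skeleton (Lee
thinning plus a simple-point cleanup of redundant 2×2 blocks).

Skeleton pixels are classified by 8-neighbour count (1 endpoint, 2 slab,
≥3 junction); adjacent junction pixels merge into one node at their
centroid, branches are traced slab-to-slab, edge length sums the pixel
steps (h axial, h√2 diagonal) and edge radius is half the mean local width
along the branch. A junction-free closed loop becomes a self-loop anchored
at its lexicographically smallest pixel. Spurs shorter than one cell
diameter ending in a degree-1 interior node are pruned, and only the
pass-through nodes pruning creates are merged (lengths add, radius is the
length-weighted mean) — a graph that was all cycles passes through
untouched.

A SOURCE and a SINK supernode are then attached: every node within one cell
diameter of a column — widened by the node's own incident vessel radius,
because the centreline of a wide vessel abutting a column retracts by half
a width — is joined to the corresponding supernode by a near-zero-resistance
edge.

Flow uses Poiseuille's law per vessel, Q = πr⁴ΔP/(8ηl), with ΔP = 1 kPa
imposed between the supernodes and η = 8.9×10⁻⁴ Pa·s (water at 25 °C).
The solver is the nodal formulation: pressures are the unknowns, zero net
flow is imposed at every interior node, and the resulting sparse symmetric
positive-definite system is solved directly; the loop law holds identically
because flows derive from a potential. The literal edge/node/loop assembly
is kept in the test suite as an independent oracle and the two formulations
agree to 10⁻⁸ relative on random graphs. Self-loops carry no flow; parallel
edges contribute independent conductances; components not containing the
terminals are at zero gauge pressure and zero flow, which automatically
silences dead-end branches and disconnected fragments.

## Phase III — factory operation

Every graph edge with a pixel path is an exchange surface, and the two
circulatory columns are always exchange surfaces of their own (carrying the
flow of a single virtual pipe joining them — the perfusion the external
circuit provides regardless of any interior network; this is also the
entire machinery of the no-network baseline). Per time step:

* nutrient enters along each surface at ρ_n·2πr·|Q|/(k_out+|Q|)·k_l/(k_l+N)
  per unit length — flow-saturating, and *demand-driven*: depleted
  microenvironments are replenished fastest;
* each producer synthesizes product at μ_p·N/(N+k_p)·k_i/(X+k_i)·M_p and
  consumes nutrient at the same form scaled by μ_n (the consumption/
  synthesis ratio is μ_n/μ_p everywhere);
* product is removed along each surface at ρ_p·2πr·|Q|/(k_in+|Q|)·X/(k_p+X)
  per unit length — stagnant vessels remove nothing;
* both fields diffuse with D_p through the shared explicit stepper.

The local value a surface sees is the mean over a 1-pixel-radius
neighbourhood of its path pixels; exchange is distributed uniformly per
unit length along the path. Sinks are clipped per pixel so neither field
ever goes negative, and the clipped uptake is attributed back to surfaces
in proportion to demand, so the per-segment ledger sums exactly to the
field mass removed: every run satisfies ΔN = delivered − consumed and
ΔX = produced − removed to ≤ 10⁻⁶ relative.

Steady state is declared when the trailing removal rate drifts less than
`steady_tol` between consecutive ~1 s detection blocks; the run then
continues for `production_window` seconds of throughput accounting.
Throughput is the product mass removed per hour (μg/h); the per-volume
variant divides by domain area times a one-cell-diameter slab depth. A
producer displays as "active" when its local nutrient exceeds k_p/10 —
a reporting threshold only, with no feedback on the dynamics.

### Kinetic calibration

The reference work models a fungal vanillin producer but publishes no
directly transferable constants, so the kinetic defaults here were
calibrated once against the qualitative behaviour the design requires —
producers adjacent to flowing vessels activate; the interior of large
lacunae starves; dense, well-drained networks benefit from inhibition
relief — and then frozen: ρ_n = ρ_p = 0.3 pg/(μm·s),
k_out = k_in = 2×10⁵ μm³/s, k_l = 1, μ_p = 2 s⁻¹, μ_n = 28 s⁻¹, k_p = 0.2,
k_i = 0.25, M_p = 1 pg, D_p = 2×10⁻¹¹ m²/s. The consumption-dominated
regime gives a nutrient penetration depth δ = √(D_p·k_p/(μ_n·ρ_cell)) of a
few μm around each perfused vessel, which is what creates the contrast
between a starved no-network culture (only a thin boundary layer along the
columns produces) and a fully-fed vascularized one. Absolute throughputs
are therefore calibration-dependent and only relative quantities
(fold-improvement over the paired baseline, the location of the optimum,
the connectivity threshold) are meaningful model outputs.

## Evaluation harness and problem sizes

The desk-scale profile (258 × 258 μm, 3000 interior cells, 390 circulatory
cells, 300 morphogenesis steps, 30 s production window) runs one full
three-phase pipeline in ~15 s and is the profile all shipped studies and
acceptance runs use; the reference-scale profile is available but takes
tens of minutes per run. Experiment seeds derive from a master seed by a
counter scheme (master + run index, mod 2³¹), so reruns and parallel splits
are reproducible; sweeps share seeds across fractions so comparisons are
paired, and each seed's no-network baseline is computed once.

Desk-scale results with the frozen defaults: fold-improvement 20–26× at
40–60% vascular fraction (reference range: 15–40×); mean relative
productivity peaks at 50%, one 10%-grid step below the reference optimum
of 60% — at this domain size the producer-loss/activity-gain trade-off
genuinely flattens between 40% and 60%, and one grid step is the documented
desk-scale tolerance; the connectivity threshold falls at 20% exactly as
in the reference narrative.

## What the synthetic data does and does not show

All inputs are generated; there is no external data. The generator
reproduces the *mechanistic* conditions of the design study — crowded
monolayer, two-species chemoattractant signalling, laminar perfusion,
Michaelis–Menten conversion with product inhibition — at a quarter of the
reference linear scale. It does not model cell division, death or
differentiation, waste species distinct from product, vessel lumenization
or compliance, pulsatile or non-Newtonian flow, 3D geometry, or the
downstream separation of product from the outflow. Passing tests therefore
demonstrate internal consistency and reproduction of the reference study's
relative claims at desk scale, not predictive accuracy for any wet-lab
system.

## Numerical choices and limitations

* Explicit diffusion steps always use 0.999× the stability bound h²/(4D)
  when not set explicitly; decay is exact-exponential; sinks are clipped,
  sources never are.
* The shoving relaxation caches its neighbour list for a few passes
  (rebuilt every 4th pass with a 1 μm slack) and tolerates residual
  overlaps of 0.05 μm; at the default ~75% packing a granular system can
  jam with slightly larger residuals, which the morphogenesis loop absorbs.
* Cell lists are plain dataclasses at the API surface and a
  struct-of-arrays mirror internally; conversions happen once per phase.
* The connectivity threshold and the optimum location are properties of a
  stochastic transition measured with 5 and 3 seeds respectively; single
  seeds can and do deviate by one grid step.
* The displacement cap of one radius per mechanical step, the 6-direction
  protrusion sampling, the down-weighted circulatory field and the
  contact-inhibition cone are all exposed in `ChemoParams` /
  `SimulationConfig`; the shipped values are the calibration freeze, and
  moving them can re-open every emergent result above.
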