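# Methods

## Model

Each blastomere i is a phase field ϕᵢ(**r**, t) on a uniform cuboid
lattice, ≈1 inside the cell, ≈0 outside; the 0.5 level set is the
membrane. A static field ϕₑ marks the eggshell (0 inside, 1 outside). The
free-energy ingredients are the Ginzburg–Landau surface energy
γ∫(½|∇ϕ|² + cW(ϕ)) with the double well W(ϕ) = ϕ²(ϕ−1)², quadratic
overlap penalties against the shell (gₑ) and other cells (g), an advective
attraction along neighbour interface normals (σᵢⱼ∇ϕⱼ), and a global volume
constraint of strength M toward the prescribed volume Vᵢ. Force densities
are the variational line densities given in the README; the net force,
balanced against viscous drag −τ**u**, advects each field:

∂ϕᵢ/∂t = −(1/τ)(F_ten + F_rep + F_atr + F_vol)·∇ϕᵢ.

Assumptions inherited from the model class: cells are purely passive
mechanical objects (no protrusions, cortical flow or active migration
machinery — the fast directed motion some blastomeres show late in the
8-cell stage is outside the model); the eggshell is rigid and static;
cytokinesis is instantaneous; viscosity is uniform; all cells share one
surface tension.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| γ | surface tension strength | 0.25 | lattice |
| c | interface-thickness coefficient | 1.0 | lattice |
| gₑ | eggshell repulsion strength | 16 | lattice |
| g | cell–cell repulsion strength | 1.6 | lattice |
| M | volume-constraint strength | 0.0012 | lattice |
| τ | viscosity coefficient | 2.62 | lattice |
| h | time step | 0.1 | model time |
| σ_W / σ_S / σ′_S | weak / strong / extra-strong adhesion | 0.2 / 0.9 / 1.6 | lattice |
| ϵ | division-split interface width | 2⁻⁵² | voxels |
| dl | reference voxel pitch | 0.2508 | μm/voxel |

All PDE arithmetic runs in lattice units; dl enters only when geometry is
constructed or lengths/areas/volumes are reported. The compressed
reference eggshell is a spheroid with semi-axes 27.5837 μm (A-P) and
18.3477 μm (D-V and, before compression, L-R), clipped by two planes at
|y − y_c| = 9.9506 μm (= 18.3477 − 16.7942/2). The unclipped L-R semi-axis
is taken equal to the D-V one; the exact agreement of the printed half
width with that arithmetic supports the choice. The uncompressed
comparison shell keeps the major axis and the enclosed volume; its minor
semi-axis has the closed form m = √(3V/4πa) because the clipped-spheroid
volume is analytic, πab(2h − 2h³/3b²).

Grid-axis assignment: the reference 256×256×128 cuboid is stored as dims
(256, 128, 256) in (x = A-P, y = L-R, z = D-V) order — the compressed L-R
axis is the only one whose 19.9 μm extent fits the 128-voxel dimension
(32.1 μm); the D-V diameter (36.7 μm) needs a 256-voxel axis.

## Numerical choices

* Spatial discretization: central differences for ∇, the compact 7-point
  stencil for Δ, replicate-edge boundaries. The eggshell keeps all cell
  mass several voxels off the domain box, so the boundary rule is inert.
* The formal force expressions are 0/0 off the interface: denominators are
  regularized (10⁻⁶) and forces are zeroed where |∇ϕ|² ≤ 10⁻⁸ — they are
  line densities defined on the membrane. F_vol uses the gradient identity
  M(∫ϕ − V)∇ϕ/|∇ϕ|, which fixes the sign without interpreting the inward
  normal.
* Time integration is explicit forward Euler; non-finite values abort with
  the offending cell and step. The fused per-step update computes
  (F·∇ϕᵢ) directly from shared per-cell gradients; a test pins it to the
  modular force functions.
* Eggshell and zygote fields are tanh profiles of an approximate signed
  distance (the normalized implicit function rescaled by its gradient
  norm), width ~2 voxels. The zygote seed fills the shell interior eroded
  to the prescribed volume: its equal-volume sphere would not fit the
  compressed shell, and seeding through the shell wall would put deep
  overlap into the first explicit steps.
* Division offset search: the positive-side mass fraction is monotone in
  the plane offset b, so bisection brackets the target; with the sharp
  default ϵ the fraction is a step function whose jumps are whole voxel
  planes (a plane hit exactly contributes half its mass), so the search
  additionally evaluates the bracketed exact plane coordinates and returns
  the L(b) minimizer. Daughters' prescribed volumes split the mother's by
  the achieved (not nominal) ratio so the volume constraint does not fight
  the split. Coarse-grid scenario configs use a finite split width
  (ϵ = 0.75 voxels) to keep the ratio continuously tunable; the reference
  config keeps ϵ = 2⁻⁵².
* Quasi-steady detection: per-cell mass-centre speeds are sampled every
  `sample_stride` steps (default 100), smoothed with a moving average
  (default 21 samples), and minima are sign changes of the first
  difference separated by at least `qss_min_separation` samples. The
  smoothing parameters are configurable; coarse grids need harder
  smoothing because their v̄ traces are noisier.
* Stage stops: pre-6-cell stages relax to mechanical equilibrium
  (v̄ below a threshold, default 2×10⁻⁴ μm per model time unit at the
  reference pitch, scaled with the voxel size); the 6- and 7-cell stages
  end at their first quasi-steady state, the 8-cell stage at its second.
  The reported stop step is the detected minimum itself; detection lags it
  by roughly the smoothing window, so divisions are applied a few samples
  after the minimum.
* Time-scale fit: simulated stage durations (steps) are regressed through
  the origin against experimental durations minus the predetermined
  cytokinesis lag Δt₀ = 2.2784 min (instantaneous bisection omits that
  phase); R² is reported on the same through-origin model.

## Scenario library and problem sizes

The library is fully self-contained. Measured per-cell volumes and
division orientations are not part of the package's sources, so the
shipped defaults are documented placeholders, tagged `provenance` in every
config: total cell volume = 0.9 × eggshell interior; AB:P1 = EMS:P2 =
55:45; C:P3 = 2:1 with C dorsal; AB-lineage and EMS splits symmetric;
axis-aligned division directions (P0 and EMS along A-P, ABp along L-R, ABa
and P2 along D-V, with the AB and P1 divisions tilted 45° in the x–z plane
so the 4-cell diamond can form). Users substitute measured values through
the YAML configs; replicate contact/area tables enter as CSV.

Desk-scale runs use coarsened grids: the 4-cell topology runs at quarter
resolution (64×32×64, dl ≈ 1.0 μm, ~2.5 min), the full 7-stage program at
1/8 pitch on a padded 38×20×38 grid (~1 min per run). These sizes were
chosen so the whole suite completes in minutes on one core. Coarsening has
physical costs: the tension/volume equilibrium of a cell sits at a volume
deficit ∝ γ/(M r V) in lattice units, i.e. ~0.5% for a 12-voxel cell but
several percent for the quarter-grid blastomeres and tens of percent for
the smallest 8-cell blastomeres at 1/8 pitch. Consequently the 4-cell
contact topology is reproduced and asserted at quarter resolution, while
the 8-cell motif comparison (ABpl-E adhesion weakening preserving the
ABpr-MS contact and the 3D structure) is run and reported at 1/8 pitch but
not hard-asserted — the cells whose contacts it concerns are barely
resolved there. Quantitative area/δ comparisons and the conserved-contact
counts belong to the reference 256×256×128 grid; `wt_compressed_full` and
the scan configs execute unmodified where that compute and the replicate
tables are available.

## What passing tests show — and do not show

The suite verifies the mechanics against independent oracles: operators
against brute-force stencils, the eggshell against analytic/Monte-Carlo
volumes, division against an exhaustive offset scan, α against a dense
parametric quadrature, areas against triangulated isosurfaces, the
detector and the time fit against planted synthetic signals, and the
4-cell topology end to end. The synthetic scenarios idealize real data:
placeholder volumes and axis-aligned orientations stand in for measured
ones, coarse grids blur small cells, and the passive-mechanics model omits
protrusive motility. Green tests therefore certify the implementation and
its discretization, not biological fidelity at reduced resolution.

## Known limitations

* The advective scheme is only approximately variational: discrete energy
  can fluctuate at the 10⁻³ level per step, and a stationary interface
  carries an O(h²) residual force (~0.03 at c = 1).
* Sharp-ϵ division cannot hit arbitrary volume ratios on a lattice; the
  achieved ratio is quantized by half voxel planes (~1% at reference
  resolution, worse when coarse).
* Explicit Euler restricts the step size; no implicit or spectral path is
  provided.
* Supported stages are 1–8 cells; later stages and gradual cytokinesis
  are out of scope.
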