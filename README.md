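# embryophase

Phase-field simulation of early *Caenorhabditis elegans* embryogenesis.

Early *C. elegans* development is stereotypic at single-cell resolution:
seven division rounds take the embryo from the zygote P0 to the 8-cell
stage along an invariant lineage (P0 → AB + P1, P1 → EMS + P2, …), with
reproducible cell positions, shapes and cell–cell contacts. `embryophase`
models each blastomere as a 3D diffuse-interface field ϕᵢ(**r**, t) ∈ [0, 1]
confined inside a rigid eggshell that is compressed along the left–right
axis (as in slide-mounted imaging). It is written for computational
biologists who want to simulate and quantify early multicellular
morphogenesis — cell arrangements, contact maps, deformation — without any
external dataset: every governing parameter ships in the scenario library.

## Model

Each cell's field is driven by four interface force densities,

    F_ten = −γ (Δϕᵢ − c W′(ϕᵢ)) ∇ϕᵢ / |∇ϕᵢ|²          surface tension
    F_rep = (gₑ ϕᵢ ϕₑ² + g ϕᵢ Σ_{j≠i} ϕⱼ²) ∇ϕᵢ / |∇ϕᵢ|²  eggshell / cell repulsion
    F_atr = Σ_{j≠i} σᵢⱼ ∇ϕⱼ                              cell–cell attraction
    F_vol = M (∫ϕᵢ d**r** − Vᵢ) ∇ϕᵢ / |∇ϕᵢ|              volume constraint

with W(ϕ) = ϕ²(ϕ−1)² the double-well potential and ϕₑ the static eggshell
field (0 inside, 1 outside). The overdamped advective dynamics

    ∂ϕᵢ/∂t = −(1/τ) (F_ten + F_rep + F_atr + F_vol) · ∇ϕᵢ

are integrated with explicit forward Euler (h = 0.1). Cytokinesis is an
instantaneous bisection of the mother field by a plane **n**·(**r**−**r**_c) = b,
with b chosen so the daughter volumes hit a prescribed ratio; the two
sigmoid factors sum to one, so the split conserves mass exactly. The
cell–cell attraction matrix is binarized (σ_W = 0.2 for sister pairs,
σ_S = 0.9 otherwise, σ′_S = 1.6 for an especially strong contact), with
single-pair "motif" overrides. Divisions fire when the embryo reaches a
quasi-steady state — a local minimum of the root-mean-square cell speed
v̄(t) — and per-stage durations convert to minutes through a proportional
fit (k time steps per minute).

Quantification follows the same conventions throughout: contact maps from
the argmax label volume (shared voxel faces × dl²), surface areas from the
∫|∇ϕ| integral, the deformation coefficient α = ∮ (R−r̄)²/(r̄²R²) ds on the
ϕ = 0.5 isosurface, the ternary conserved-contact classification across
replicates, developmental-path signatures (deduplicated contact-map
sequences), and the L-R embryo width that diagnoses structural
planarization.

## Worked example

Run the 1-to-4-cell wild-type program at quarter resolution (64×32×64
voxels, ~2–3 min on one core) and read off the diamond topology:

```python
import embryophase as ep

cfg = ep.builtin("fourcell_emsp2_scan", grid_divisor=4).variants[1]  # σ_EMS,P2 = 0.2
result = cfg.run()
cmap = ep.contact_map(result.embryo)
print(sorted(tuple(sorted(p)) for p in cmap.pairs))
print({ "-".join(sorted(p)): round(a, 1) for p, a in cmap.areas.items() })
```

prints

```
[('ABa', 'ABp'), ('ABa', 'EMS'), ('ABp', 'EMS'), ('ABp', 'P2'), ('EMS', 'P2')]
{'ABa-ABp': 634.0, 'ABa-EMS': 183.2, 'ABp-EMS': 207.3, 'ABp-P2': 265.7, 'EMS-P2': 444.8}
```

— the five contacts of the diamond-shaped 4-cell arrangement with their
areas in μm²; the anterior ABa and posterior P2 never touch. Desk-scale
conversions work the same way:

```python
>>> fit = ep.TimescaleFit(k=1.6735e4, r_squared=0.9993, delta_t0=2.2784)
>>> round(ep.steps_to_minutes(150500, fit), 2)
8.99
>>> ep.half_width_from_compression(18.3477, 16.7942)
9.9506
```

A thin CLI wraps the same library calls:

```bash
embryophase scenarios list
embryophase simulate --scenario toy_single --out runs/toy
embryophase analyze --run runs/toy
embryophase sweep --scenario fourcell_sigma_scan --grid-divisor 4 --out runs/scan
```

The scenario library also carries the full-resolution reference
configuration (`wt_compressed_full`, 256×256×128 voxels at dl = 0.2508 μm
with the fitted constants γ = 0.25, c = 1, gₑ = 16, g = 1.6, M = 0.0012,
τ = 2.62), the equal-volume uncompressed-eggshell variant, the attraction
scans (σ ∈ {0…1.5}, σ_EMS,P2 ∈ {0…0.8}, 17 single 8-cell motifs), the
division-timing tree and the 3×3 P2 orientation grid. Reduced-grid runs
are qualitative; quantitative statements hold at the reference grid.

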