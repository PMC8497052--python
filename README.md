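# dryveg

Trait-structured reaction–diffusion modelling of dryland plant
communities: how water stress reshapes community composition and
functional diversity, and how spatial self-organisation (vegetation
patterning) pushes back.

## The model

A community of `N` plant functional groups is arranged along a
dimensionless tradeoff trait `χ ∈ (0, 1]`: `χ → 0` species invest in
shoot growth (high light-capture capacity `K`, high mortality `M`,
strong contribution `Y` to water infiltration), `χ → 1` species invest
in tolerating water stress (low `K`, `M`, `Y`), with all three traits
linear in `χ`. Group biomasses `B_i(x, t)` are coupled to soil water
`W(x, t)` and surface water `H(x, t)` on a 1-D periodic domain:

    ∂t B_i = Λ_i W B_i − M_i B_i + D_B ∂x² B_i + D_χ ∂χ² B_i
    ∂t W   = I H − L W − Γ W Σ_j B_j + D_W ∂x² W
    ∂t H   = P − I H + D_H ∂x² H

with light-limited growth `Λ_i = Λ₀ K_i / (B̄ + K_i)`, biomass-enhanced
infiltration `I = A (B̿ + f Q)/(B̿ + Q)` (`B̄ = Σ B_j`, `B̿ = Σ Y_j B_j`),
shading-reduced evaporation `L = L₀/(1 + R B̄)`, and a discrete trait
Laplacian `∂χ² B_i = N² (B_{i+1} − 2B_i + B_{i−1})` representing rare
mutations to neighbouring groups at rate `D_χ`. Differential
infiltration routes surface water towards denser vegetation — the
scale-dependent feedback that destabilises uniform vegetation into
periodic (Turing) patterns as precipitation `P` drops.

The package provides:

- `dryveg.model` — parameters, trait grid, rate functions, tendencies;
- `dryveg.uniform` — stiff integration of the spatially decoupled
  system to its mutation–selection equilibrium (the uniform community);
- `dryveg.stability` — equilibria, bare-soil threshold `P_B = M L₀/Λ₀`,
  dispersion relations, Turing threshold `P_T` and critical wavelength,
  branch tracing by precipitation sweeps;
- `dryveg.spatial` / `dryveg.steady` — trajectory-accurate (BDF, sparse
  analytic Jacobian) and steady-state (pseudo-transient, block-tridiagonal
  direct solves) integrators of the full PDE system, plus initial-condition
  generators;
- `dryveg.metrics` — composition `χ_max`, functional richness `FR`
  (trait width above a seedling biomass density), Shannon analogue `H′`
  and Pielou evenness `FE = H′/ln N`;
- `dryveg.scenarios` — the four standard experiments (emergence,
  precipitation downshift, branch buffering, hybrid states) as
  reproducible pipelines with manifests.

## Worked example

```python
from dryveg import ModelParams, build_trait_grid, turing_point
from dryveg.uniform import uniform_branch

params = ModelParams()                      # standard constants, P in mm/y
grid = build_trait_grid(params.N, params)   # N = 128 functional groups

PT, kc, wavelength = turing_point(1.0, params)
print(f"P_T = {PT:.2f} mm/y, wavelength = {wavelength:.1f} m")

table = uniform_branch([150.0, 100.0], grid, params)
print(table[["P", "chi_max", "FR", "FE", "total_biomass"]])
```

prints

```
P_T = 92.95 mm/y, wavelength = 75.7 m
       P   chi_max        FR        FE  total_biomass
0  150.0  0.617188  0.299834  0.622116       0.160044
1  100.0  0.773438  0.260228  0.600636       0.085308
```

Uniform vegetation of the most stress-tolerant group (`χ = 1`) loses
stability to ~76 m periodic patterns below `P_T ≈ 93` mm/y. The
assembled uniform community shifts from a most-abundant trait of 0.62
at 150 mm/y to 0.78 at 100 mm/y while its functional richness drops
from 0.30 to 0.26 — drying pushes uniform communities towards stress
tolerance and erodes diversity. Running the spatial model at 80 mm/y
(`dryveg.scenarios.run_downshift`) reverses both trends: the patterned
community re-centres near `χ_max ≈ 0.66` with richness ≈ 0.28 and a
higher total biomass than the (unstable) uniform state.

A command-line interface mirrors the main entry points:

```sh
dryveg stability --chi 1.0
dryveg scenario downshift --outdir runs/downshift --seed 1
dryveg metrics distribution.csv --sensitivity
```

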