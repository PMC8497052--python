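# Methods

## Model

The model couples `N` functional-group biomasses `B_i` to soil water
`W` and surface water `H` (all kg/m²) on a 1-D periodic domain.
Precipitation `P` is treated as a constant parameter; 1 mm of rain is
1 kg/m² of water, so mm/y and kg/(m²·y) are used interchangeably. The
trait `χ_i = i/N` encodes a growth/stress-tolerance tradeoff through
linear relations `K(χ) = K_max + χ(K_min − K_max)` (light-capture
capacity), `M(χ)` (mortality) and `Y(χ)` (infiltration contribution),
each decreasing in `χ`. The fitness of group `i` is `Λ_i W − M_i`: low
mortality lets high-`χ` groups stay viable at lower soil-water
content, which is what "stress tolerance" means here.

`B_i` is the biomass of one trait interval `Δχ = 1/N`, not a density
per unit trait: its amplitude shrinks as `1/N` while the density
`b_i = N·B_i` converges with `N`. Metrics that compare against an
absolute biomass level (the seedling threshold of the richness metric)
therefore act on `b_i`; without that convention no absolute threshold
could give an `N`-independent width.

Default constants (standard values): `Λ₀ = 0.032 m²/(kg·y)`,
`Γ = 20 m²/(kg·y)`, `f = 0.01`, `A = 40/y`, `Q = 0.06 kg/m²`,
`L₀ = 4/y`, `R = 10 m²/kg`, `K ∈ [0.1, 0.6] kg/m²`, `M ∈ [0.5, 0.9]/y`,
`Y ∈ [0.5, 1.5]`, `N = 128`, `D_B = 1 m²/y`, `D_W = 10² m²/y`,
`D_H = 10⁴ m²/y`, `D_χ = 10⁻⁶/y`, `α = 0`. Overland flow is kept in
its linear-diffusion limit (`α = 0`); the nonlinear exponent is
retained as a parameter and supported by the explicit tendency
evaluation, but the implicit integrators require `α = 0`.

Trait-axis boundaries use reflecting ghost bins (`B₀ = B₁`,
`B_{N+1} = B_N`), a zero-flux closure that makes trait diffusion
conserve biomass exactly (the operator output sums to zero to machine
precision). The bin-level discretisation of zero flux is not uniquely
determined by the continuum statement; reflection was chosen for its
exact conservation property.

## Uniform (spatially decoupled) assembly

Dropping spatial derivatives leaves `N + 2` ODEs whose time scales
span nine orders of magnitude: hydrology relaxes within fractions of
a year, competitive exclusion takes 10²–10⁵ y, and the
mutation–selection balance equilibrates on `1/D_χ = 10⁶ y`.
Integration uses scipy's BDF with a dense analytic Jacobian,
geometrically growing checkpoint times, and a stationarity criterion
`max|dB_i/dt| < 10⁻⁹ · max(B_i)` that may not be declared before a
minimum horizon of `10/D_χ` years (the slowest relevant time scale);
the hard horizon is `2·10⁷ y`. Initial conditions seed every group at
a floor of `10⁻³ kg/m²` (viable seeds of all groups are assumed
present; the asymptotic community is insensitive to the floor level —
tested against `10⁻⁶`). Precipitation sweeps re-seed vanished groups
at `10⁻¹⁰ kg/m²` between stages so that re-assembly remains possible;
each stage starts from the previous equilibrium (continuation by
sweeping), which also lets the sweep follow the uniform branch below
the Turing threshold where the spatial system would pattern.

## Spatial integration

Method of lines: second-order central differences on a uniform
periodic grid, all fields advanced together. Two integrators share
one analytic Jacobian, which is block-tridiagonal (one dense
`(N+2)×(N+2)` reaction block per grid point, diagonal diffusive
coupling blocks, periodic corners):

* `spatial.integrate` — scipy BDF with the sparse Jacobian;
  trajectory-accurate, used wherever transient dynamics or threshold
  behaviour matter (pattern emergence near `P_T`, conservation and
  symmetry checks).
* `steady.settle` — adaptive backward-Euler pseudo-transient
  relaxation with a modified Newton iteration and a direct
  block-Thomas/bordered solver for the periodic block-tridiagonal
  systems. The per-step relative change of any field is capped (5%)
  so the physical transient is tracked; the step grows geometrically
  as the dynamics die out, ending in Newton convergence to the steady
  state. This is ~10–30× faster than BDF on community-scale problems
  and is what the scenario pipelines use.

Caveat of the steady-state finder: backward Euler damps *growing*
modes once `dt·σ ≫ 1`, so an instability much slower than the
resolved dynamics can be stepped over and the relaxation may stop on
a weakly unstable state. Near instability thresholds the BDF
integrator is used instead (and the test suite checks threshold
behaviour only with it).

Implicit solvers can undershoot zero at machine-precision level;
negative values beyond `−10⁻¹⁰` abort the run, smaller ones are
clipped and logged.

Default spatial domains hold a whole number (2–4) of Turing
wavelengths, so periodic boundaries admit the critical mode, at 24
grid points per wavelength (halving `dx` changes the asymptotic norm
by < 1% and the detected wavelength by less than one coarse cell).
Initial-condition noise is additive and uniform on biomass only, with
amplitude relative to the field mean and a seeded generator
(bit-reproducible).

## Single-group stability analysis

The single-group model (all `B_i ≡ 0` except one, trait diffusion
off) has the bare-soil equilibrium `(0, P/L₀, P/(fA))` at every `P`
and vegetated equilibria found by collapsing the three balance
equations to one scalar equation in `B` (bracketed scan + Brent).
Linearising about bare soil gives the closed-form stability threshold
`P_B(χ) = M(χ)·L₀/Λ₀` (62.5 mm/y at `χ = 1`, 112.5 at `χ = 0`). The
dispersion relation evaluates the largest eigenvalue real part of the
3×3 reaction Jacobian minus `k²·diag(D_B, D_W, D_H)` on 200
log-spaced wavenumbers (wavelengths 5–500 m) with local refinement of
the maximum; the Turing point bisects `P` for the zero of the maximal
growth rate. For the standard constants this gives `P_T(1) = 92.95
mm/y` with critical wavelength `2π/k_c = 75.7 m`, and `P_T(0) = 118.9
mm/y` — growth-investing species pattern at higher precipitation, and
patterns form at 80 mm/y but not at 100. The 75.7 m wavelength is
confirmed by direct simulation: on a 1000 m domain the pattern
emerging from noise just below `P_T` selects 76.9 m = 1000/13, the
nearest admissible mode. Branch tracing uses hysteresis-aware
precipitation sweeps with time integration; unstable branches are not
reachable this way (a deliberate limitation — no pseudo-arclength
continuation is attempted), and stability is assessed by whether the
state persists under perturbed integration.

## Diversity metrics

`χ_max` is the trait of the bin with maximal space-averaged biomass
(ties break to lower `χ`). Functional richness `FR` is the trait
width of the region whose density `b(χ)` exceeds a seedling level
(default `10⁻³ kg/m²`, configuration-exposed), with linear
interpolation of the edge crossings to remove grid dependence; a
threshold-sensitivity table can be emitted since the seedling level
is the one free choice in this metric. The Shannon analogue
`H′ = −Σ b̂_i ln b̂_i` uses normalised biomass shares, and the Pielou
evenness is `FE = H′/ln N` with the full grid size `N` including
empty bins. `χ_max` and `FR` are practically `N`-independent (< 2%
between `N = 64` and 128); `FE` is not — refining the grid twofold
adds exactly `ln 2` to `H′` for the same smooth density, so `FE`
values are only comparable at equal `N`. All `FE` comparisons in the
experiments therefore run at the standard `N = 128`.

## Scenario pipelines

* Emergence (`P = 180`): decoupled model with `D_χ = 0` (competitive
  exclusion; ≤ 2 groups hold 99% of biomass) vs `D_χ = 10⁻⁶`
  (finite-width community, tens of groups above the seedling level).
* Downshift (150 → 100 → 80): stages seeded from the previous
  asymptotic state. Stages with `P` above `P_T(χ=1)` — the most
  pattern-resistant group's threshold, used as the conservative
  criterion — run the decoupled model; below it the spatial model
  runs on a 4-wavelength domain, seeded by tiling the last uniform
  community plus `10⁻³` relative noise. The decoupled equilibrium is
  also computed at spatial stages for the biomass comparison.
* Buffering: precipitation sweep down a patterned branch
  (4-wavelength domain). A perfectly periodic state is an invariant
  manifold of the deterministic dynamics, so a tiny seeded biomass
  perturbation is re-applied each stage; without it patch-elimination
  instabilities could never be expressed. The default sweep
  (89 → 54 mm/y) covers the branch stretch where composition is
  buffered (`χ_max` constant to within one trait bin); continuing
  deeper, the community slowly drifts to higher `χ` before the
  wavelength-halving transition near 34 mm/y (richness change across
  the transition < 0.01) and collapse near 20 mm/y.
* Hybrid states (`P = 100`, inside the bistability range
  `P_T < P` where uniform vegetation is stable but patterns exist):
  the patterned community state is generated by relaxing a fully
  modulated (cosine at the Turing wavelength) uniform community — a
  stand-in for a continued periodic solution as the seed within the
  subcritical range. Composites embed a patterned window (fraction of
  whole wavelengths) in the uniform state and are relaxed to
  stationarity. Domains are classified by local one-wavelength
  standard deviation of total biomass exceeding 10% of the local
  mean; front pinning is verified by continuing the integration 2000 y
  and measuring boundary displacement. Outcomes that collapse to a
  pure state are recorded as such, not errors.

All pipelines are deterministic given their seed; manifests (JSON)
record parameters, seeds and grid sizes, and re-running from a
manifest reproduces metrics to < 10⁻⁶ (noise is bit-identical).

## Problem sizes

Full-scale runs (`N = 128`, 4-wavelength domains, 24 points per
wavelength) complete in seconds (uniform assembly, stability
analysis) to about a minute (hybrid pipeline). The test suite
exercises the scenario invariants at `N = 64` on 2-wavelength domains
— the package's scaled standard test configuration — and the headline
anchor values at full `N = 128`.

## Known limitations

- No two-dimensional domains (gap/labyrinth/spot morphologies out of
  scope), no terrain slope, no nonlinear overland flow in the
  implicit integrators.
- No numerical continuation of unstable or snaking branches; branch
  structure is explored only through stable attractors of time
  integration.
- The steady-state finder can mistake weakly unstable states for
  attractors near thresholds (see above).
- `FE` retains an intrinsic `ln N` dependence; cross-resolution
  comparisons of evenness are not meaningful.
- The continuum limit `N → ∞` is not implemented as a separate
  solver; the discrete trait grid stands in for it.
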