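# Methods

## The model

`thrombosim` simulates arterial platelet thrombus growth as a continuum
adsorption process. Platelets are not tracked individually; the aggregate
is a dimensionless bound-platelet concentration `C ∈ [0, c_max]`
(`c_max = 1` after nondimensionalization) that grows by attachment of
suspended platelets to two kinds of binding sites on the existing
aggregate: the "side planes" of already-bound particles (a volumetric
term `C/λ`, with `λ` the particle size) and the "free ends" of partially
built layers (a surface term `|∇C|`). Saturation of binding space enters
through the factor `(1 − C/c_max)`. Attachment is irreversible;
detachment and activation biochemistry are deliberately absent (they are
absorbed into the effective rate constant).

### 1D family (`core_1d`)

    ∂C/∂t = k_eff (1 − C/c_max) (C/λ + |∂C/∂x|)        "full"
    ∂C/∂t = k_eff (1 − C/c_max) |∂C/∂x|                "bet"   (single site)
    ∂C/∂t = −k_eff ∂C/∂x                               "rosen" (no saturation)

`k_eff` (m/s) lumps hematocrit, shear rate, molecular on-rates and the
free-platelet concentration. The "bet" variant is the classical
single-binding-site multilayer-adsorption reduction; "rosen" drops
saturation altogether and is exact advection at speed `k_eff` — our main
analytic oracle. There is no diffusion term anywhere, by construction:
bound platelets do not diffuse.

A front seeded at a substrate (Dirichlet `C = c_max` at the left node)
propagates rightward as a wave of fixed shape. Its speed is measured as
the growth rate of the profile integral, `V = d(∫C dx)/dt`, by central
differences over recorded snapshots, with the plateau value averaged over
the last third of snapshots whose front stays at least 10 cells clear of
the right boundary.

### 2D coupled problem (`flow_2d`, `thrombus_2d`)

In a rectangular channel (height `M = 50 µm`, length `L = 150 µm`) the
concentration obeys

    ∂C/∂t = k_adh γ (1 − C/c_max) (C/λ + |∇C|) − k_rol ∇·(v̄ C)

with `γ` the local shear rate of the surrounding flow (`k_eff → k_adh γ`,
`k_adh` in m), and a conservative convection term scaled by the platelet
movability `k_rol` that lets the flow rearrange loosely bound platelets
along the aggregate surface. Boundary conditions: `C = 0` at the inlet,
zero normal gradient at the outlet and both walls. The injury is a strip
of wall cells initialized at `C = 1` (an initial condition, not a
sustained source: those cells evolve freely afterwards).

Plasma is a Newtonian incompressible fluid (`ρ = 1060 kg/m³`,
`ν = 5e-6 m²/s`) with no-slip walls, driven either by a fixed pressure
drop `Δp = 30 Pa` between the inlet and outlet planes or by a fixed
parabolic inlet profile with wall shear rate `1000 1/s` (peak
`γ_w M/4 = 12.5 mm/s`); in plane Poiseuille flow the two drivings are
nearly equivalent (`Δp M/(2ρνL) ≈ 943 1/s`).

Wherever `C ≥ c_b` (`c_b = 0.9`) the cell joins a rigid obstacle: all of
its velocity faces are pinned to zero (first-order stairstep immersed
boundary) and the pressure equation closes with a Neumann condition
across its faces. Convection consequently vanishes identically inside
the aggregate; fluid penetrates only the sub-threshold rim.

Reference coefficients (torch-shaped growth regime): `λ = 3 µm`,
`k_adh = 8e-11 m`, `k_rol = 7e-5`, `c_b = 0.9`, injury length
`l0 = 15 µm` centered on the bottom wall.

## Numerics

**1D.** Uniform grid of node values at `x_i = i·dx`; forward Euler with
the CFL-type bound `dt ≤ s·dx/(k_eff(1 + dx/λ))`, safety `s = 0.5` by
default. The gradient magnitude uses the backward (substrate-side)
one-sided difference — the Godunov upwind choice for an expanding front;
central differencing is unstable for gradient-magnitude terms. Values are
clipped to `[0, c_max]` after each step to remove the `O(dt²)` Euler
overshoot. Default discretization: 100 µm domain, 200 nodes
(`dx = 0.5 µm`).

**Flow.** MAC staggered grid (`u` on vertical faces, `v` on horizontal
faces, `p` at centers), default `dx = dy = 1 µm`. Tangential velocity
ghosts at no-slip walls use the quadratic half-cell extrapolation
`u_g = −2u_0 + u_1/3`, which makes plane Poiseuille an exact solution of
the discrete operators; the obstacle stairstep remains first order.
Because the channel Reynolds number is ≈ 0.1 and the flow relaxes in
`M²/ν ≈ 0.5 ms` while growth takes seconds, the production path computes
the steady flow directly: one sparse LU solve of the steady Stokes saddle
system (velocities + pressures simultaneously), re-done only when the
obstacle mask changes or every `n_refresh = 100` concentration steps.
A time-marching Chorin projection (explicit advection–diffusion
predictor, pressure-Poisson with Dirichlet pressures on the open planes
and Neumann closures on walls/obstacle, divergence-free corrector) is
retained as the verification mode; the two agree to < 2% on every tested
obstacle, and the post-projection divergence vanishes to solver rounding
(scaled residual ≲ 1e-10). A steady solve whose continuity residual
exceeds `1e-6` of the driving scale is rejected as ill-posed (this
happens exactly when a fixed-flux driving meets a blocking obstacle
chain).

`γ` is the cell-centered rate-of-strain magnitude `sqrt(2 D:D)`, which
reduces to `|du/dy|` in unidirectional flow and hence equals the wall
shear rate at the walls; a `|du/dy|`-only mode is available for
sensitivity checks. Whether the original formulation evaluated `γ`
field-wide or at the obstacle surface only is not determinable from its
description; the local-strain choice is the one that makes the equation
well-defined pointwise.

**2D concentration.** Godunov upwinding for `|∇C|` (one-sided difference
kept only when it looks toward the high-concentration side, per axis);
conservative upwind face fluxes for `∇·(v̄C)`. The adhesion gradient uses
the stated boundary ghosts (Dirichlet 0 at the inlet); the convective
fluxes use interior-copy ghosts at open boundaries so that a uniform
field is exactly invariant under a divergence-free flow. Step size
`dt ≤ 0.5·min(dx/(k_adh γ_max(1 + dx/λ)), dx/(k_rol |v̄|_max))`,
recomputed at every flow refresh. Operator order within a step is fixed:
flow → γ → concentration (explicit Euler + clip) → mask, so the obstacle
always lags the concentration by one step and the per-step flow problem
stays well-posed. Inside the obstacle `C` keeps evolving by the adhesion
term alone (convection is zero there by construction); it is not frozen.
The mask threshold is inclusive (`C ≥ c_b`) and the masked set never
shrinks.

## Problem sizes used in tests and in `scripts/acceptance.py`

The behavioral 2D runs use a half-resolution channel (75 × 25 cells,
`dx = 2 µm`) and horizons of 200 s (shape comparisons), 450 s
(driving-condition contrast, kept short of full occlusion) and 500 s
(injury-size comparison); at these sizes a full run costs a few seconds
and the qualitative regimes (downstream-elongated torch shape, its
disappearance at `k_rol = 0`, decelerating growth under fixed `Δp` vs
accelerating growth under fixed flux, injury-size insensitivity with a
final area ratio ≈ 1.1) are already unambiguous. The solver-contract
checks run at the reference `ny = 50` cross-resolution. Everything is
deterministic; the acceptance script's `--seed` only perturbs the field
used to exercise the projection contract.

## Known limitations and deliberate properties

* **Grid-selected front speed.** Without diffusion the continuum 1D
  equation admits a one-parameter family of front speeds: a leading-edge
  profile `C ~ exp(−(x−Vt)/ℓ)` solves the linearized equation with
  `V = k_eff(1 + ℓ/λ)` for every decay length `ℓ`. The first-order
  upwind scheme selects `ℓ = O(dx)`, so the measured plateau speed
  exceeds `k_eff` by an `O(dx/λ)` margin and decreases monotonically
  toward `k_eff` under refinement rather than converging at fixed order
  (measured `V/k_eff` at λ = 1 µm: 2.49, 1.94, 1.62, 1.42, 1.30 for
  dx = 2, 1, 0.5, 0.25, 0.125 µm). Any explicit finite-difference
  treatment of this equation shares the property. Relative speeds are
  nevertheless robust: linearity in `k_eff` is exact (rescaling `t` by
  `k_eff` leaves the equation invariant), and the no-saturation variant
  reproduces `V = k_eff` to machine precision through a telescoping
  flux identity.
* **Front steepness vs λ.** The traveling-wave balance gives the slope
  profile `s(C) = k_eff C(1−C)/(λ(V − k_eff(1−C)))`: the maximum slope
  scales like `1/λ` (measured 2.3e5, 1.6e5, 1.25e5 1/m for λ = 1, 2,
  3 µm) while the 0.1–0.9 transition width grows with λ (4.8, 7.4,
  9.4 µm). "Steeper" in the sense of a sharper front therefore belongs
  to *smaller* particles; the width of the transition zone is what grows
  with λ. Both diagnostics are reported by `front_steepness`. Note that
  steepness cannot depend on `k_eff` at all, by the exact time-rescaling
  invariance above.
* **Self-limiting occlusion under fixed flux.** Adhesion is
  shear-driven, so the last open cell of a cross section loses its flow
  — and its growth — before reaching `c_b`: the channel approaches but
  never completes a seal under the velocity-profile driving. Horizons for
  the driving-condition comparison are chosen before this regime.
* The fluid inside the aggregate is simply absent (no Darcy seepage);
  platelet activation states, fibrin, and explicit embolization are out
  of scope; the near-wall platelet excess of real blood is folded into
  the rate constants; the geometry is 2D.
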