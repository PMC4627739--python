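# thrombosim

Continuum simulation of arterial platelet thrombus growth.

When an arteriole wall is injured, platelets adhere to the exposed site
and to each other, building an aggregate that protrudes into the flow.
`thrombosim` models this with a *spatial adsorption equation*: instead of
tracking cells, the aggregate is a bound-platelet concentration
`C(x, t) ∈ [0, 1]` whose growth rate combines a volumetric binding-site
term and a surface term, throttled by saturation — and, notably, contains
no diffusion:

    ∂C/∂t = k_eff (1 − C/C_max) (C/λ + |∂C/∂x|)                       (1D)

    ∂C/∂t = k_adh γ (1 − C/C_max) (C/λ + |∇C|) − k_rol ∇·(v̄ C)        (2D)

Here `λ` is the platelet size, `k_eff` (m/s) an effective adhesion
efficiency, `γ` the local shear rate of the surrounding plasma flow,
`k_adh` (m) the shear-scaled adhesion coefficient and `k_rol` the
movability of loosely bound platelets by the flow. In 2D the plasma is an
incompressible Newtonian fluid in a channel (Navier–Stokes + continuity,
solved by Chorin projection / steady Stokes on a staggered grid), and any
cell whose concentration reaches the threshold `C_B` becomes part of a
rigid, impermeable obstacle that reshapes the flow.

The package is for researchers in computational hemostasis and adsorption
modeling who want a small, fully deterministic, analyzable testbed: 1D
traveling fronts and their classical reductions (a single-binding-site
multilayer variant and the no-saturation pure-advection variant), and the
coupled 2D problem that reproduces the downstream-elongated "torch"
shape of arterial thrombi, its dependence on `k_rol`, the contrast
between fixed-pressure-drop and fixed-flux drivings, and the weak
dependence of late-stage thrombus size on injury size.

See `docs/methods.md` for the discretizations, parameter table and known
limitations.

## Worked example

One-dimensional front at the reference parameters (λ = 1 µm,
k_eff = 5·10⁻⁷ m/s, 100 µm domain):

```text
$ thrombosim run-1d --set numerics.t_end=50.0 --out runs/demo1d
plateau velocity: 8.08446e-07 m/s
artifacts in runs/demo1d
```

The front travels at a constant ≈ 0.8 µm/s — faster than `k_eff` because
the `C/λ` term feeds the leading edge — and the profile translates
without changing shape. The velocity is exactly linear in `k_eff`:

```text
$ thrombosim sweep --param model_1d.k_eff --values 2.5e-7,5e-7,7.5e-7,1e-6 \
      --set numerics.t_end=50.0 --out runs/sweep
...
model_1d.k_eff = 1e-06 -> plateau velocity 1.63789e-06 m/s
linear fit: slope 1.66156, intercept -2.254e-08, R^2 1.00000
```

Coupled 2D growth in a 150 × 50 µm channel (here at 2 µm resolution,
pressure-drop driving, reference coefficients):

```text
$ thrombosim run-2d --set grid.nx=75 --set grid.ny=25 \
      --set numerics.t_end=200.0 --set numerics.n_refresh=50 --out runs/demo2d
final thrombus area: 1.56e-10 m^2 (167 steps, 27 flow solves)
artifacts in runs/demo2d
```

After 200 simulated seconds the aggregate (cells with `C ≥ 0.9`) covers
156 µm² and extends 36 µm downstream of the injury midpoint but only
6 µm upstream — the torch shape. Re-running with
`--set thrombus.k_rol=0` removes the convective platelet transport and
with it the downstream bias. `metrics_2d.csv` holds the tidy time series
(cross-section growth velocity, area, extents, height); snapshots are CSV
grids, optionally VTK (`--set "output.formats=[csv, vtk]"`).

Built-in analytic oracles (plane Poiseuille recovery, projection
divergence, wall shear rate, pure-advection front speed):

```text
$ thrombosim validate
poiseuille_recovery_rel_err  1.119e-09  (< 1e-02)  PASS
scaled_divergence            3.608e-09  (< 1e-08)  PASS
wall_shear_rel_err           1.067e-11  (< 1e-02)  PASS
advection_plateau_rel_err    7.835e-15  (< 1e-06)  PASS
```

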