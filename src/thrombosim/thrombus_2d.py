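"""2D thrombus growth: shear-dependent adhesion coupled to channel flow.

The bound-platelet concentration ``C(x, y, t)`` evolves by

    dC/dt = k_adh * gamma * (1 - C/c_max) * (C/lambda + |grad C|)
            - k_rol * div(v C)

where ``gamma`` is the local shear rate of the surrounding flow (the 1D
adhesion efficiency ``k_eff`` is replaced by ``k_adh * gamma``) and the
conservative convection term, scaled by the platelet movability ``k_rol``,
lets the flow rearrange loosely bound platelets along the aggregate
surface.  Boundary conditions: ``C = 0`` at the inlet, zero gradient at
the outlet and both walls.  The injury is an initial condition — a strip
of wall-adjacent cells at ``C = 1`` — not a sustained source.

Wherever ``C`` reaches the threshold ``c_b`` the cell joins the rigid
obstacle: its velocity faces are zeroed, so convection vanishes inside the
aggregate and the flow sees a growing stairstep body.  Because flow
relaxation (milliseconds) is far faster than growth (seconds), the driver
recomputes the steady flow only when the mask changes (quasi-steady mode),
with a fully explicit co-stepping mode retained for verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from thrombosim.flow_2d import (
    ChannelGrid2D,
    FlowBC,
    FlowField,
    FlowSolverError,
    FluidParams,
    ObstacleMask,
    PressurePoisson,
    chorin_step,
    max_stable_dt_flow,
    shear_rate_field,
    solve_steady_flow,
)

__all__ = [
    "ThrombusParams",
    "InjurySpec",
    "CoupledState",
    "CoupledTrajectory",
    "init_injury",
    "concentration_rhs_2d",
    "apply_concentration_bcs",
    "update_mask",
    "max_stable_dt_concentration",
    "simulate_coupled",
]


@dataclass(frozen=True)
class ThrombusParams:
    """Coefficients of the 2D adhesion–convection equation.

    Defaults reproduce the reference torch-shaped growth regime.
    """

    k_adh: float = 8e-11  # adhesion coefficient, m (k_adh * gamma has units m/s)
    k_rol: float = 7e-5  # platelet movability within the aggregate, dimensionless
    lambda_len: float = 3e-6  # particle size, m
    c_b: float = 0.9  # obstacle threshold, dimensionless
    c_max: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_adh", "k_rol", "lambda_len", "c_b", "c_max"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.k_adh > 0 and self.lambda_len > 0 and self.c_max > 0):
            raise ValueError("k_adh, lambda_len and c_max must be > 0")
        if not (0 < self.c_b <= self.c_max):
            raise ValueError(
                f"c_b must lie in (0, c_max]; got c_b={self.c_b}, "
                f"c_max={self.c_max}"
            )


@dataclass(frozen=True)
class InjurySpec:
    """Injured segment of the bottom wall D.

    ``center`` defaults to mid-wall and also fixes the cross-section
    abscissa ``l*`` used by the 2D wave-velocity metric.
    """

    l0: float = 15e-6  # injury length, m
    center: float | None = None  # position along wall D, m (None = L/2)

    def __post_init__(self) -> None:
        if not self.l0 > 0:
            raise ValueError("l0 must be > 0")

    def resolved_center(self, grid: ChannelGrid2D) -> float:
        return 0.5 * grid.length if self.center is None else self.center

    def bounds(self, grid: ChannelGrid2D) -> tuple[float, float]:
        c = self.resolved_center(grid)
        return c - 0.5 * self.l0, c + 0.5 * self.l0


@dataclass
class CoupledState:
    """Concentration + flow + obstacle mask at one instant."""

    concentration: np.ndarray  # (nx, ny), cell centers
    flow: FlowField
    mask: ObstacleMask
    time: float = 0.0

    def copy(self) -> "CoupledState":
        return CoupledState(
            self.concentration.copy(),
            self.flow.copy(),
            ObstacleMask(self.mask.cells.copy()),
            self.time,
        )


@dataclass
class CoupledTrajectory:
    """Recorded coupled snapshots plus run diagnostics."""

    snapshots: list[CoupledState]
    grid: ChannelGrid2D
    params: ThrombusParams
    injury_center: float
    outlet_reached: bool = False
    #: run halted early because the obstacle occluded a full cross section
    #: under the fixed-flux boundary condition (no steady flow exists then)
    occluded: bool = False
    flow_refreshes: int = 0
    n_steps: int = 0

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])


def init_injury(grid: ChannelGrid2D, injury: InjurySpec) -> np.ndarray:
    """Injury initial condition: ``C = 1`` on the wall-adjacent cells
    whose centers fall in the injured segment, 0 elsewhere."""
    lo, hi = injury.bounds(grid)
    if lo < -1e-12 or hi > grid.length + 1e-12:
        raise ValueError(
            f"injury [{lo:g}, {hi:g}] m extends outside the wall "
            f"[0, {grid.length:g}] m"
        )
    c = np.zeros((grid.nx, grid.ny))
    x = grid.x_centers
    # half-open interval so that the default geometry covers exactly
    # l0/dx cells
    sel = (x >= lo - 1e-12) & (x < hi - 1e-12)
    c[sel, 0] = 1.0
    return c


def apply_concentration_bcs(
    c: np.ndarray, grid: ChannelGrid2D | None = None
) -> np.ndarray:
    """Ghost-padded concentration implementing the boundary conditions:
    Dirichlet 0 at the inlet ghost column, zero-gradient (copy) ghosts at
    the outlet and both walls.

    Accepts a raw ``(nx, ny)`` field (padded and filled) or — when
    ``grid`` is given — an already padded ``(nx+2, ny+2)`` array whose
    ghosts are refreshed, so that reapplying is idempotent.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2:
        raise ValueError("concentration must be 2D")
    if grid is not None and c.shape == (grid.nx + 2, grid.ny + 2):
        padded = c.copy()
    else:
        if grid is not None and c.shape != (grid.nx, grid.ny):
            raise ValueError(
                f"shape {c.shape} matches neither the raw nor the padded "
                f"field of a {grid.nx} x {grid.ny} grid"
            )
        padded = np.empty((c.shape[0] + 2, c.shape[1] + 2))
        padded[1:-1, 1:-1] = c
    interior = padded[1:-1, 1:-1]
    padded[0, 1:-1] = 0.0  # inlet A: Dirichlet 0
    padded[-1, 1:-1] = interior[-1, :]  # outlet B: zero gradient
    padded[1:-1, 0] = interior[:, 0]  # wall D
    padded[1:-1, -1] = interior[:, -1]  # wall C
    # corners (unused by the 5-point stencils; keep finite)
    padded[0, 0] = padded[0, 1]
    padded[0, -1] = padded[0, -2]
    padded[-1, 0] = padded[-1, 1]
    padded[-1, -1] = padded[-1, -2]
    return padded


def _godunov_gradient_magnitude(cp: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Upwind |grad C| for a growing front: each one-sided difference is
    kept only when it looks toward the high-concentration side."""
    dxm = (cp[1:-1, 1:-1] - cp[:-2, 1:-1]) / dx
    dxp = (cp[2:, 1:-1] - cp[1:-1, 1:-1]) / dx
    dym = (cp[1:-1, 1:-1] - cp[1:-1, :-2]) / dy
    dyp = (cp[1:-1, 2:] - cp[1:-1, 1:-1]) / dy
    return np.sqrt(
        np.minimum(dxm, 0.0) ** 2
        + np.maximum(dxp, 0.0) ** 2
        + np.minimum(dym, 0.0) ** 2
        + np.maximum(dyp, 0.0) ** 2
    )


def concentration_rhs_2d(
    c: np.ndarray,
    flow: FlowField,
    gamma: np.ndarray,
    params: ThrombusParams,
    grid: ChannelGrid2D,
) -> np.ndarray:
    """Rate of change (1/s) of the bound-platelet concentration.

    Adhesion uses the Godunov-upwind gradient magnitude; convection uses
    conservative upwind face fluxes of ``v C``.  Faces of obstacle cells
    carry zero velocity, so the convective term vanishes identically
    inside the aggregate.
    """
    nx, ny, dx, dy = grid.nx, grid.ny, grid.dx, grid.dy
    c = np.asarray(c, dtype=float)
    if c.shape != (nx, ny):
        raise ValueError(f"concentration shape {c.shape} != {(nx, ny)}")
    if gamma.shape != (nx, ny):
        raise ValueError(f"gamma shape {gamma.shape} != {(nx, ny)}")
    if flow.u.shape != (nx + 1, ny):
        raise ValueError("flow does not match the grid")

    cp = apply_concentration_bcs(c)
    grad = _godunov_gradient_magnitude(cp, dx, dy)
    adhesion = (
        params.k_adh
        * gamma
        * (1.0 - c / params.c_max)
        * (c / params.lambda_len + grad)
    )

    # conservative upwind fluxes of vC.  Open-boundary ghosts for the
    # convective term copy the interior value (so a uniform field is
    # exactly invariant under any divergence-free flow); the inlet
    # Dirichlet ghost applies to the adhesion gradient only.
    u, v = flow.u, flow.v
    cc = np.pad(c, 1, mode="edge")
    c_west = cc[:-1, 1:-1]  # C of the cell west of each u-face
    c_east = cc[1:, 1:-1]
    fx = u * np.where(u >= 0.0, c_west, c_east)
    c_south = cc[1:-1, :-1]
    c_north = cc[1:-1, 1:]
    fy = v * np.where(v >= 0.0, c_south, c_north)
    conv = (fx[1:, :] - fx[:-1, :]) / dx + (fy[:, 1:] - fy[:, :-1]) / dy
    return adhesion - params.k_rol * conv


def update_mask(
    c: np.ndarray, c_b: float, previous: ObstacleMask | None = None
) -> tuple[ObstacleMask, bool]:
    """Obstacle mask ``C >= c_b`` (inclusive threshold) and a flag saying
    whether it differs from ``previous`` (True when previous is None)."""
    cells = np.asarray(c) >= c_b
    mask = ObstacleMask(cells)
    changed = previous is None or not np.array_equal(cells, previous.cells)
    return mask, changed


def max_stable_dt_concentration(
    grid: ChannelGrid2D,
    params: ThrombusParams,
    gamma_max: float,
    speed_max: float,
    safety: float = 0.5,
) -> float:
    """Explicit-update bound
    ``safety * min(dx/(k_adh gamma_max (1 + dx/lambda)),
    dx/(k_rol |v|_max))``."""
    h = min(grid.dx, grid.dy)
    bounds = []
    if gamma_max > 0:
        bounds.append(h / (params.k_adh * gamma_max * (1.0 + h / params.lambda_len)))
    if params.k_rol > 0 and speed_max > 0:
        bounds.append(h / (params.k_rol * speed_max))
    if not bounds:
        return np.inf
    return safety * min(bounds)


def simulate_coupled(
    grid: ChannelGrid2D,
    fluid: FluidParams,
    bc: FlowBC,
    params: ThrombusParams,
    injury: InjurySpec | None,
    t_end: float,
    dt: float | None = None,
    record_every: float | None = None,
    mode: str = "quasi_steady",
    n_refresh: int = 100,
    shear_mode: str = "strain",
    safety: float = 0.5,
) -> CoupledTrajectory:
    """Integrate the coupled growth problem to ``t_end``.

    Per step: (1) refresh the steady flow if the obstacle mask changed
    since the last refresh or ``n_refresh`` steps elapsed (quasi-steady
    mode) or co-step the flow explicitly (``mode="explicit"``,
    verification only); (2) compute the shear-rate field; (3) explicit
    Euler concentration update with its boundary conditions, clipped to
    ``[0, c_max]``; (4) update the mask.

    Returns the recorded trajectory; ``outlet_reached`` flags the obstacle
    contacting the outlet column.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if mode not in ("quasi_steady", "explicit"):
        raise ValueError(f"unknown mode {mode!r}")

    if injury is None:  # uninjured wall: zero initial concentration
        c = np.zeros((grid.nx, grid.ny))
        center = 0.5 * grid.length
    else:
        c = init_injury(grid, injury)
        center = injury.resolved_center(grid)
    mask, _ = update_mask(c, params.c_b)
    flow = solve_steady_flow(fluid, grid, bc, mask)
    gamma = shear_rate_field(flow, mode=shear_mode)
    state = CoupledState(c, flow, mask, 0.0)
    traj = CoupledTrajectory([state.copy()], grid, params, center)
    traj.flow_refreshes = 1
    if t_end == 0:
        return traj

    def stable_dt() -> float:
        d = max_stable_dt_concentration(
            grid, params, float(gamma.max()), flow.max_speed(), safety=safety
        )
        if dt is not None:
            d = min(d, dt)
        if record_every is not None:
            d = min(d, record_every)
        if not np.isfinite(d):
            d = t_end / 10.0
        return d

    step_dt = stable_dt()
    if record_every is None:
        record_every = t_end / 10.0
    next_record = record_every
    steps_since_refresh = 0
    t = 0.0
    poisson = None
    while t < t_end - 1e-12:
        h = min(step_dt, t_end - t)
        rate = concentration_rhs_2d(c, flow, gamma, params, grid)
        c = np.clip(c + h * rate, 0.0, params.c_max)
        t += h
        mask, changed = update_mask(c, params.c_b, previous=mask)
        steps_since_refresh += 1
        fully_occluded = bool(mask.cells.all(axis=1).any())
        if fully_occluded and bc.variant == "velocity_profile":
            # a fixed inlet flux cannot pass a blocked cross section;
            # halt and record the state reached
            traj.occluded = True
            traj.snapshots.append(
                CoupledState(c.copy(), flow.copy(), ObstacleMask(mask.cells.copy()), t)
            )
            break
        if mode == "quasi_steady":
            if changed or steps_since_refresh >= n_refresh:
                try:
                    flow = solve_steady_flow(fluid, grid, bc, mask)
                except FlowSolverError:
                    # flow problem became ill-posed (e.g. a blocking chain
                    # of obstacle cells under fixed flux): halt here
                    traj.occluded = True
                    traj.snapshots.append(
                        CoupledState(
                            c.copy(), flow.copy(),
                            ObstacleMask(mask.cells.copy()), t,
                        )
                    )
                    break
                gamma = shear_rate_field(flow, mode=shear_mode)
                traj.flow_refreshes += 1
                steps_since_refresh = 0
                step_dt = stable_dt()
        else:  # fully explicit co-stepping (verification)
            if changed or poisson is None:
                poisson = PressurePoisson(grid, mask, bc)
            remaining = h
            while remaining > 1e-18:
                fdt = min(
                    max_stable_dt_flow(flow, fluid, safety=0.4), remaining
                )
                flow = chorin_step(flow, fluid, fdt, bc, mask, poisson=poisson)
                remaining -= fdt
            gamma = shear_rate_field(flow, mode=shear_mode)
            step_dt = stable_dt()
        traj.n_steps += 1
        if not traj.outlet_reached and mask.cells[-1, :].any():
            traj.outlet_reached = True
        if t >= next_record - 1e-12 or t >= t_end - 1e-12:
            traj.snapshots.append(
                CoupledState(c.copy(), flow.copy(), ObstacleMask(mask.cells.copy()), t)
            )
            next_record += record_every
    return traj
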