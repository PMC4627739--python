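"""Incompressible channel flow around a growing rigid obstacle.

Blood plasma is treated as a Newtonian incompressible fluid in a 2D
rectangular channel (inlet A at x=0, outlet B at x=L, top wall C, bottom
wall D), governed by the Navier-Stokes equations with no-slip walls.  The
thrombus enters as a per-cell obstacle mask: every velocity face of a
masked cell is held at exactly zero, realizing the aggregate as a rigid,
impermeable stairstep body.

Discretization is the standard MAC staggered arrangement:

* ``u[i, j]`` at vertical faces ``(i*dx, (j+0.5)*dy)``, shape (nx+1, ny)
* ``v[i, j]`` at horizontal faces ``((i+0.5)*dx, j*dy)``, shape (nx, ny+1)
* ``p[i, j]`` at cell centers, shape (nx, ny)

Two inlet/outlet drivings are supported: a fixed pressure drop ``delta_p``
between the inlet and outlet planes, or a fixed parabolic inlet velocity
profile parameterized by its wall shear rate.  Time integration uses the
Chorin projection (explicit predictor, pressure Poisson, divergence-free
corrector); since the flow relaxes on millisecond scales while the
thrombus grows over seconds, the production path is a direct steady-Stokes
solve (`solve_steady_flow`), with the explicit march retained for
verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "FluidParams",
    "ChannelGrid2D",
    "FlowField",
    "FlowBC",
    "ObstacleMask",
    "poiseuille_analytic",
    "apply_flow_bcs",
    "chorin_step",
    "solve_steady_flow",
    "shear_rate_field",
    "divergence",
    "max_stable_dt_flow",
    "PressurePoisson",
    "FlowSolverError",
]


class FlowSolverError(RuntimeError):
    """The flow solve failed (singular or non-convergent system), e.g. a
    fully occluded channel under a fixed-flux boundary condition."""


@dataclass(frozen=True)
class FluidParams:
    """Newtonian fluid properties of blood plasma."""

    rho: float = 1060.0  # density, kg/m^3
    nu: float = 5e-6  # kinematic viscosity, m^2/s

    def __post_init__(self) -> None:
        if not (self.rho > 0 and self.nu > 0):
            raise ValueError("rho and nu must both be > 0")


@dataclass(frozen=True)
class ChannelGrid2D:
    """Uniform rectangular channel grid (x along the flow, y across)."""

    length: float = 15e-5  # L, m
    height: float = 5e-5  # M, m
    nx: int = 150
    ny: int = 50

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.height > 0):
            raise ValueError("length and height must be > 0")
        if self.nx < 2 or self.ny < 2:
            raise ValueError("nx and ny must be >= 2")

    @property
    def dx(self) -> float:
        return self.length / self.nx

    @property
    def dy(self) -> float:
        return self.height / self.ny

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy


@dataclass(frozen=True)
class FlowBC:
    """Inlet/outlet driving of the channel.

    ``pressure_gradient`` imposes Dirichlet pressures differing by
    ``delta_p`` on the inlet/outlet planes with zero-gradient velocity;
    ``velocity_profile`` imposes a parabolic inlet with wall shear rate
    ``wall_shear`` (peak velocity ``wall_shear * M / 4``) and a
    zero-reference-pressure outflow.
    """

    variant: str = "pressure_gradient"
    delta_p: float = 30.0  # Pa
    wall_shear: float = 1000.0  # 1/s

    def __post_init__(self) -> None:
        if self.variant not in ("pressure_gradient", "velocity_profile"):
            raise ValueError(f"unknown flow BC variant {self.variant!r}")
        if self.variant == "pressure_gradient" and not self.delta_p >= 0:
            raise ValueError("delta_p must be >= 0")
        if self.variant == "velocity_profile" and not self.wall_shear > 0:
            raise ValueError("wall_shear must be > 0")

    def inlet_profile(self, grid: ChannelGrid2D) -> np.ndarray:
        """Parabolic inlet u(y) with wall slope ``wall_shear`` at u-face
        centers (velocity_profile variant)."""
        y = grid.y_centers
        m = grid.height
        return self.wall_shear * y * (m - y) / m


@dataclass
class ObstacleMask:
    """Boolean per-cell mask marking thrombus-as-rigid-obstacle cells."""

    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.cells.ndim != 2:
            raise ValueError("mask must be 2D (nx, ny)")

    @classmethod
    def empty(cls, grid: ChannelGrid2D) -> "ObstacleMask":
        return cls(np.zeros((grid.nx, grid.ny), dtype=bool))

    @property
    def any(self) -> bool:
        return bool(self.cells.any())

    def u_faces(self) -> np.ndarray:
        """Mask of u-faces adjacent to at least one masked cell,
        shape (nx+1, ny)."""
        nx, ny = self.cells.shape
        m = np.zeros((nx + 1, ny), dtype=bool)
        m[:-1] |= self.cells
        m[1:] |= self.cells
        return m

    def v_faces(self) -> np.ndarray:
        """Mask of v-faces adjacent to at least one masked cell,
        shape (nx, ny+1)."""
        nx, ny = self.cells.shape
        m = np.zeros((nx, ny + 1), dtype=bool)
        m[:, :-1] |= self.cells
        m[:, 1:] |= self.cells
        return m

    def enclosed_cells(self) -> np.ndarray:
        """Unmasked cells whose four faces are all masked (isolated
        cavities); their pressure is decoupled and must be pinned."""
        uf, vf = self.u_faces(), self.v_faces()
        return (~self.cells) & uf[:-1] & uf[1:] & vf[:, :-1] & vf[:, 1:]

    def key(self) -> bytes:
        return self.cells.tobytes()


@dataclass
class FlowField:
    """Staggered-grid velocity and cell-centered pressure."""

    grid: ChannelGrid2D
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        g = self.grid
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.u.shape != (g.nx + 1, g.ny):
            raise ValueError(f"u shape {self.u.shape} != {(g.nx + 1, g.ny)}")
        if self.v.shape != (g.nx, g.ny + 1):
            raise ValueError(f"v shape {self.v.shape} != {(g.nx, g.ny + 1)}")
        if self.p.shape != (g.nx, g.ny):
            raise ValueError(f"p shape {self.p.shape} != {(g.nx, g.ny)}")

    @classmethod
    def zeros(cls, grid: ChannelGrid2D) -> "FlowField":
        return cls(
            grid,
            np.zeros((grid.nx + 1, grid.ny)),
            np.zeros((grid.nx, grid.ny + 1)),
            np.zeros((grid.nx, grid.ny)),
        )

    def copy(self) -> "FlowField":
        return FlowField(
            self.grid, self.u.copy(), self.v.copy(), self.p.copy(), self.time
        )

    def max_speed(self) -> float:
        return float(max(np.abs(self.u).max(), np.abs(self.v).max()))

    def cell_center_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        """Face velocities averaged to cell centers, each (nx, ny)."""
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        return uc, vc


def poiseuille_analytic(
    params: FluidParams, grid: ChannelGrid2D, delta_p: float
) -> FlowField:
    """Plane Poiseuille flow driven by pressure drop ``delta_p`` over the
    channel length: ``u(y) = delta_p/(2 rho nu L) * y (M - y)``, v = 0,
    linear pressure, evaluated at the staggered face/center locations."""
    g = grid
    gcoef = delta_p / (2.0 * params.rho * params.nu * g.length)
    y = g.y_centers
    u = np.tile(gcoef * y * (g.height - y), (g.nx + 1, 1))
    v = np.zeros((g.nx, g.ny + 1))
    p = np.tile(
        delta_p * (1.0 - g.x_centers / g.length)[:, None], (1, g.ny)
    )
    return FlowField(g, u, v, p)


def apply_flow_bcs(
    flow: FlowField, bc: FlowBC, mask: ObstacleMask | None = None
) -> FlowField:
    """Return a copy with no-slip and inlet/outlet conditions enforced.

    Zeroes the wall-normal velocity on walls C/D and every face of masked
    cells; for the velocity_profile variant also sets the parabolic inlet
    and a zero-gradient outflow.
    """
    out = flow.copy()
    g = flow.grid
    out.v[:, 0] = 0.0
    out.v[:, -1] = 0.0
    if bc.variant == "velocity_profile":
        out.u[0, :] = bc.inlet_profile(g)
        out.u[-1, :] = out.u[-2, :]
    if mask is not None and mask.any:
        out.u[mask.u_faces()] = 0.0
        out.v[mask.v_faces()] = 0.0
    return out


# ---------------------------------------------------------------------------
# Ghost conventions.  Tangential velocity at a no-slip wall half a cell away
# uses the quadratic extrapolation ghost = -2*f0 + f1/3 (exact for parabolic
# profiles); zero-gradient open boundaries copy the interior value.


def _u_ghost_wall(u0: np.ndarray, u1: np.ndarray) -> np.ndarray:
    return -2.0 * u0 + u1 / 3.0


def divergence(flow: FlowField) -> np.ndarray:
    """Discrete per-cell divergence (1/s), shape (nx, ny)."""
    g = flow.grid
    return (flow.u[1:, :] - flow.u[:-1, :]) / g.dx + (
        flow.v[:, 1:] - flow.v[:, :-1]
    ) / g.dy


def shear_rate_field(flow: FlowField, mode: str = "strain") -> np.ndarray:
    """Cell-centered shear rate gamma (1/s).

    ``mode="strain"`` (default): magnitude of the rate-of-strain tensor,
    ``sqrt(2 D:D) = sqrt(2 du/dx^2 + 2 dv/dy^2 + (du/dy + dv/dx)^2)``,
    which reduces to ``|du/dy|`` in unidirectional flow and therefore
    equals the wall shear rate at the walls.  ``mode="dudy"``: the
    ``|du/dy|`` cross term only, for sensitivity checks.
    """
    g = flow.grid
    nx, ny, dx, dy = g.nx, g.ny, g.dx, g.dy
    u, v = flow.u, flow.v

    dudx = (u[1:, :] - u[:-1, :]) / dx  # (nx, ny) at centers
    dvdy = (v[:, 1:] - v[:, :-1]) / dy

    # du/dy at corners (nx+1, ny+1), walls via quadratic no-slip ghosts
    dudy_c = np.empty((nx + 1, ny + 1))
    dudy_c[:, 1:-1] = (u[:, 1:] - u[:, :-1]) / dy
    gbot = _u_ghost_wall(u[:, 0], u[:, 1])
    gtop = _u_ghost_wall(u[:, -1], u[:, -2])
    dudy_c[:, 0] = (u[:, 0] - gbot) / dy
    dudy_c[:, -1] = (gtop - u[:, -1]) / dy

    # dv/dx at corners; zero-gradient ghosts at the open ends
    dvdx_c = np.empty((nx + 1, ny + 1))
    dvdx_c[1:-1, :] = (v[1:, :] - v[:-1, :]) / dx
    dvdx_c[0, :] = 0.0
    dvdx_c[-1, :] = 0.0

    cross_c = dudy_c + dvdx_c
    cross = 0.25 * (
        cross_c[:-1, :-1] + cross_c[1:, :-1] + cross_c[:-1, 1:] + cross_c[1:, 1:]
    )
    if mode == "dudy":
        dudy = 0.25 * (
            dudy_c[:-1, :-1] + dudy_c[1:, :-1] + dudy_c[:-1, 1:] + dudy_c[1:, 1:]
        )
        return np.abs(dudy)
    if mode != "strain":
        raise ValueError(f"unknown shear mode {mode!r}")
    return np.sqrt(2.0 * dudx**2 + 2.0 * dvdy**2 + cross**2)


def max_stable_dt_flow(
    flow: FlowField, params: FluidParams, safety: float = 0.5
) -> float:
    """Explicit-marching bound ``safety * min(h^2/(4 nu), h/|u|_max)``."""
    g = flow.grid
    h = min(g.dx, g.dy)
    dt = h * h / (4.0 * params.nu)
    umax = flow.max_speed()
    if umax > 0:
        dt = min(dt, h / umax)
    return safety * dt


# ---------------------------------------------------------------------------
# Pressure Poisson operator (shared by the projection step)


class PressurePoisson:
    """Factorized pressure-Poisson operator for a fixed grid/mask/BC.

    Dirichlet pressure on the inlet plane (pressure_gradient variant only)
    and on the outlet plane; homogeneous Neumann on walls and across every
    masked face.  Masked and enclosed cells are pinned to p = 0.
    """

    def __init__(self, grid: ChannelGrid2D, mask: ObstacleMask, bc: FlowBC):
        self.grid = grid
        self.bc = bc
        nx, ny, dx, dy = grid.nx, grid.ny, grid.dx, grid.dy
        uf, vf = mask.u_faces(), mask.v_faces()
        pinned = mask.cells | mask.enclosed_cells()
        self.pinned = pinned
        n = nx * ny
        idx = lambda i, j: i * ny + j

        rows, cols, vals = [], [], []
        # RHS contribution of the Dirichlet boundary pressures, as
        # multipliers of (p_in, p_out)
        self.rhs_in = np.zeros(n)
        self.rhs_out = np.zeros(n)
        ax, ay = 1.0 / dx**2, 1.0 / dy**2
        for i in range(nx):
            for j in range(ny):
                k = idx(i, j)
                if pinned[i, j]:
                    rows.append(k); cols.append(k); vals.append(1.0)
                    continue
                diag = 0.0
                # west
                if not uf[i, j]:
                    if i == 0:
                        if bc.variant == "pressure_gradient":
                            diag -= 2.0 * ax
                            self.rhs_in[k] -= 2.0 * ax
                        # velocity_profile: Dirichlet u at inlet -> Neumann p
                    else:
                        diag -= ax
                        rows.append(k); cols.append(idx(i - 1, j)); vals.append(ax)
                # east
                if not uf[i + 1, j]:
                    if i == nx - 1:
                        diag -= 2.0 * ax
                        self.rhs_out[k] -= 2.0 * ax
                    else:
                        diag -= ax
                        rows.append(k); cols.append(idx(i + 1, j)); vals.append(ax)
                # south (wall D at j=0: Neumann)
                if j > 0 and not vf[i, j]:
                    diag -= ay
                    rows.append(k); cols.append(idx(i, j - 1)); vals.append(ay)
                # north (wall C: Neumann)
                if j < ny - 1 and not vf[i, j + 1]:
                    diag -= ay
                    rows.append(k); cols.append(idx(i, j + 1)); vals.append(ay)
                if diag == 0.0:
                    # fully isolated cell (should have been pinned)
                    diag = 1.0
                rows.append(k); cols.append(k); vals.append(diag)
        a = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        self.lu = spla.splu(a)

    def solve(self, rhs_cells: np.ndarray, p_in: float, p_out: float) -> np.ndarray:
        """Solve ``lap p = rhs`` with the stored BCs; rhs shape (nx, ny)."""
        nx, ny = self.grid.nx, self.grid.ny
        b = rhs_cells.reshape(nx * ny).astype(float).copy()
        b[self.pinned.reshape(-1)] = 0.0
        b += self.rhs_in * p_in + self.rhs_out * p_out
        p = self.lu.solve(b)
        return p.reshape(nx, ny)


def _boundary_pressures(bc: FlowBC) -> tuple[float, float]:
    if bc.variant == "pressure_gradient":
        return bc.delta_p, 0.0
    return 0.0, 0.0


def chorin_step(
    flow: FlowField,
    params: FluidParams,
    dt: float,
    bc: FlowBC,
    mask: ObstacleMask | None = None,
    poisson: PressurePoisson | None = None,
) -> FlowField:
    """One projection cycle: explicit predictor (advection + diffusion),
    pressure-Poisson solve, divergence-free corrector.

    Faces of masked cells are excluded from both prediction and correction
    and stay exactly zero; the post-step divergence of every open cell
    vanishes to the accuracy of the sparse direct solve.
    """
    g = flow.grid
    if mask is None:
        mask = ObstacleMask.empty(g)
    hard = max_stable_dt_flow(flow, params, safety=1.0)
    if dt <= 0 or dt > hard * (1 + 1e-12):
        raise ValueError(
            f"dt = {dt:g} s outside the stability bound {hard:g} s"
        )
    nx, ny, dx, dy = g.nx, g.ny, g.dx, g.dy
    nu = params.nu
    rho = params.rho
    flow = apply_flow_bcs(flow, bc, mask)
    u, v = flow.u, flow.v
    uf, vf = mask.u_faces(), mask.v_faces()
    p_in, p_out = _boundary_pressures(bc)

    # --- ghost-extended u: x zero-gradient at the open ends, quadratic
    # no-slip ghosts below/above the walls
    ue = np.empty((nx + 3, ny + 2))
    ue[1:-1, 1:-1] = u
    ue[0, 1:-1] = u[0, :]
    ue[-1, 1:-1] = u[-1, :]
    ue[:, 0] = _u_ghost_wall(ue[:, 1], ue[:, 2])
    ue[:, -1] = _u_ghost_wall(ue[:, -2], ue[:, -3])

    ve = np.empty((nx + 2, ny + 1))
    ve[1:-1, :] = v
    if bc.variant == "velocity_profile":
        ve[0, :] = _u_ghost_wall(v[0, :], v[1, :])  # v = 0 on the inlet plane
    else:
        ve[0, :] = v[0, :]
    ve[-1, :] = v[-1, :]

    # --- predictor for u (all faces; Dirichlet inlet reimposed later)
    lap_u = (ue[2:, 1:-1] - 2 * ue[1:-1, 1:-1] + ue[:-2, 1:-1]) / dx**2 + (
        ue[1:-1, 2:] - 2 * ue[1:-1, 1:-1] + ue[1:-1, :-2]
    ) / dy**2
    dudx = (ue[2:, 1:-1] - ue[:-2, 1:-1]) / (2 * dx)
    dudy = (ue[1:-1, 2:] - ue[1:-1, :-2]) / (2 * dy)
    # v averaged to u locations: four surrounding v faces (ghost columns
    # supply the boundary faces)
    v_at_u = 0.25 * (
        ve[:-1, :-1] + ve[:-1, 1:] + ve[1:, :-1] + ve[1:, 1:]
    )
    adv_u = u * dudx + v_at_u * dudy
    u_star = u + dt * (-adv_u + nu * lap_u)

    # --- predictor for v (interior horizontal faces only)
    lap_v = np.zeros_like(v)
    adv_v = np.zeros_like(v)
    lap_v[:, 1:-1] = (
        ve[2:, 1:-1] - 2 * ve[1:-1, 1:-1] + ve[:-2, 1:-1]
    ) / dx**2 + (v[:, 2:] - 2 * v[:, 1:-1] + v[:, :-2]) / dy**2
    dvdx = (ve[2:, :] - ve[:-2, :]) / (2 * dx)
    dvdy = np.zeros_like(v)
    dvdy[:, 1:-1] = (v[:, 2:] - v[:, :-2]) / (2 * dy)
    # u averaged to v locations
    u_at_v = np.zeros_like(v)
    u_at_v[:, 1:-1] = 0.25 * (
        u[:-1, 1:] + u[1:, 1:] + u[:-1, :-1] + u[1:, :-1]
    )
    adv_v[:, 1:-1] = (u_at_v * dvdx + v * dvdy)[:, 1:-1]
    v_star = v + dt * (-adv_v + nu * lap_v)
    v_star[:, 0] = 0.0
    v_star[:, -1] = 0.0
    if bc.variant == "velocity_profile":
        u_star[0, :] = bc.inlet_profile(g)
        u_star[-1, :] = u_star[-2, :]
    u_star[uf] = 0.0
    v_star[vf] = 0.0

    # --- pressure Poisson
    if poisson is None:
        poisson = PressurePoisson(g, mask, bc)
    div_star = (u_star[1:, :] - u_star[:-1, :]) / dx + (
        v_star[:, 1:] - v_star[:, :-1]
    ) / dy
    p = poisson.solve(rho / dt * div_star, p_in, p_out)

    # --- corrector on open faces only
    u_new = u_star.copy()
    v_new = v_star.copy()
    u_new[1:-1, :] -= dt / rho * (p[1:, :] - p[:-1, :]) / dx
    if bc.variant == "pressure_gradient":
        u_new[0, :] -= dt / rho * 2.0 * (p[0, :] - p_in) / dx
    u_new[-1, :] -= dt / rho * 2.0 * (p_out - p[-1, :]) / dx
    v_new[:, 1:-1] -= dt / rho * (p[:, 1:] - p[:, :-1]) / dy
    if bc.variant == "velocity_profile":
        u_new[0, :] = bc.inlet_profile(g)
    u_new[uf] = 0.0
    v_new[vf] = 0.0
    v_new[:, 0] = 0.0
    v_new[:, -1] = 0.0
    p_full = p.copy()
    p_full[poisson.pinned] = 0.0
    return FlowField(g, u_new, v_new, p_full, flow.time + dt)


# ---------------------------------------------------------------------------
# Direct steady-Stokes solve


def _assemble_stokes(
    params: FluidParams,
    grid: ChannelGrid2D,
    bc: FlowBC,
    mask: ObstacleMask,
) -> tuple[sp.csc_matrix, np.ndarray]:
    """Sparse steady-Stokes saddle system on the staggered grid.

    Unknowns: all u faces, all v faces, all cell pressures.  Momentum rows
    use the same ghost conventions as the projection step; continuity rows
    close the system; masked faces, wall v-faces, masked/enclosed-cell
    pressures get identity rows.
    """
    nx, ny, dx, dy = grid.nx, grid.ny, grid.dx, grid.dy
    nu_, rho = params.nu, params.rho
    uf, vf = mask.u_faces(), mask.v_faces()
    pinned_p = mask.cells | mask.enclosed_cells()

    n_u = (nx + 1) * ny
    n_v = nx * (ny + 1)
    n_p = nx * ny
    iu = lambda i, j: i * ny + j
    iv = lambda i, j: n_u + i * (ny + 1) + j
    ip = lambda i, j: n_u + n_v + i * ny + j

    rows, cols, vals = [], [], []
    b = np.zeros(n_u + n_v + n_p)

    def add(r, c, vv):
        rows.append(r); cols.append(c); vals.append(vv)

    ax, ay = nu_ / dx**2, nu_ / dy**2
    p_in, p_out = _boundary_pressures(bc)
    inlet_u = bc.inlet_profile(grid) if bc.variant == "velocity_profile" else None

    # ---- u momentum
    for i in range(nx + 1):
        for j in range(ny):
            r = iu(i, j)
            if uf[i, j]:
                add(r, r, 1.0)
                continue
            if bc.variant == "velocity_profile" and i == 0:
                add(r, r, 1.0)
                b[r] = inlet_u[j]
                continue
            diag = 0.0
            # x-diffusion
            if i > 0:
                add(r, iu(i - 1, j), ax); diag -= ax
            # i == 0: zero-gradient ghost (no contribution)
            if i < nx:
                add(r, iu(i + 1, j), ax); diag -= ax
            # y-diffusion with quadratic wall ghosts
            if j == 0:
                add(r, iu(i, 1), (4.0 / 3.0) * ay); diag -= 4.0 * ay
            elif j == ny - 1:
                add(r, iu(i, ny - 2), (4.0 / 3.0) * ay); diag -= 4.0 * ay
            else:
                add(r, iu(i, j - 1), ay)
                add(r, iu(i, j + 1), ay)
                diag -= 2.0 * ay
            add(r, r, diag)
            # pressure gradient
            if i == 0:
                add(r, ip(0, j), -2.0 / (rho * dx))
                b[r] = -2.0 * p_in / (rho * dx)
            elif i == nx:
                add(r, ip(nx - 1, j), 2.0 / (rho * dx))
                b[r] = 2.0 * p_out / (rho * dx)
            else:
                add(r, ip(i, j), -1.0 / (rho * dx))
                add(r, ip(i - 1, j), 1.0 / (rho * dx))

    # ---- v momentum
    for i in range(nx):
        for j in range(ny + 1):
            r = iv(i, j)
            if j == 0 or j == ny or vf[i, j]:
                add(r, r, 1.0)
                continue
            diag = 0.0
            # x-diffusion
            if i == 0:
                if bc.variant == "velocity_profile":
                    # v = 0 on the inlet plane: quadratic ghost
                    add(r, iv(1, j), (4.0 / 3.0) * ax); diag -= 4.0 * ax
                else:
                    add(r, iv(1, j), ax); diag -= ax  # zero-gradient ghost
            elif i == nx - 1:
                add(r, iv(nx - 2, j), ax); diag -= ax  # zero-gradient ghost
            else:
                add(r, iv(i - 1, j), ax)
                add(r, iv(i + 1, j), ax)
                diag -= 2.0 * ax
            # y-diffusion (neighbors exist: j in 1..ny-1)
            add(r, iv(i, j - 1), ay)
            add(r, iv(i, j + 1), ay)
            diag -= 2.0 * ay
            add(r, r, diag)
            add(r, ip(i, j), -1.0 / (rho * dy))
            add(r, ip(i, j - 1), 1.0 / (rho * dy))

    # ---- continuity / pinned pressure
    for i in range(nx):
        for j in range(ny):
            r = ip(i, j)
            if pinned_p[i, j]:
                add(r, r, 1.0)
                continue
            add(r, iu(i + 1, j), 1.0 / dx)
            add(r, iu(i, j), -1.0 / dx)
            add(r, iv(i, j + 1), 1.0 / dy)
            add(r, iv(i, j), -1.0 / dy)

    n = n_u + n_v + n_p
    a = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return a, b


def solve_steady_flow(
    params: FluidParams,
    grid: ChannelGrid2D,
    bc: FlowBC,
    mask: ObstacleMask | None = None,
    tol: float = 1e-10,
    mode: str = "stokes",
    max_iter: int = 200_000,
) -> FlowField:
    """Steady channel flow around the masked obstacle.

    ``mode="stokes"`` (default): one direct sparse solve of the steady
    Stokes system — the faithful limit at the channel's Reynolds number
    (~0.1) and the production path of the coupled growth driver.
    ``mode="march"``: explicit Chorin projection marched until the
    relative max-norm change per unit time step falls below ``tol``
    (verification mode; use small grids).
    """
    if mask is None:
        mask = ObstacleMask.empty(grid)
    if not tol > 0:
        raise ValueError("tol must be > 0")
    if mode == "stokes":
        a, b = _assemble_stokes(params, grid, bc, mask)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error", spla.MatrixRankWarning)
            try:
                sol = spla.spsolve(a, b)
            except spla.MatrixRankWarning as exc:
                raise FlowSolverError(
                    "steady Stokes system is singular (fully occluded "
                    "channel under a fixed-flux boundary condition?)"
                ) from exc
        if not np.all(np.isfinite(sol)):
            raise FlowSolverError("steady Stokes solve returned non-finite values")
        n_u = (grid.nx + 1) * grid.ny
        n_v = grid.nx * (grid.ny + 1)
        u = sol[:n_u].reshape(grid.nx + 1, grid.ny)
        v = sol[n_u : n_u + n_v].reshape(grid.nx, grid.ny + 1)
        p = sol[n_u + n_v :].reshape(grid.nx, grid.ny)
        flow = FlowField(grid, u, v, p)
        # enforce the exact zeros the solution already satisfies to
        # rounding (identity rows): masked faces and wall-normal velocity
        flow.u[mask.u_faces()] = 0.0
        flow.v[mask.v_faces()] = 0.0
        flow.v[:, 0] = 0.0
        flow.v[:, -1] = 0.0
        # a near-singular system (e.g. fixed flux into a blocked channel)
        # yields a finite but mass-violating "solution": reject it.  The
        # violation is measured against the driving velocity scale so a
        # legitimately stagnant solution (fully blocked fixed-Δp channel)
        # passes.
        u_ref = max(
            flow.max_speed(),
            bc.delta_p * grid.height**2 / (8 * params.rho * params.nu * grid.length)
            if bc.variant == "pressure_gradient"
            else bc.wall_shear * grid.height / 4,
        )
        if u_ref > 0:
            div = np.abs(divergence(flow)[~mask.cells]).max()
            if div > 1e-6 * u_ref / min(grid.dx, grid.dy):
                raise FlowSolverError(
                    "steady Stokes solution violates continuity "
                    f"(scaled divergence {div * min(grid.dx, grid.dy) / u_ref:.2e}); "
                    "the flow problem is ill-posed for this mask/BC combination"
                )
        return flow
    if mode != "march":
        raise ValueError(f"unknown mode {mode!r}")

    flow = apply_flow_bcs(FlowField.zeros(grid), bc, mask)
    poisson = PressurePoisson(grid, mask, bc)
    check_every = 25
    prev = flow.copy()
    for it in range(max_iter):
        dt = max_stable_dt_flow(flow, params, safety=0.4)
        flow = chorin_step(flow, params, dt, bc, mask, poisson=poisson)
        if (it + 1) % check_every == 0:
            scale = max(flow.max_speed(), 1e-30)
            du = np.abs(flow.u - prev.u).max()
            dv = np.abs(flow.v - prev.v).max()
            if max(du, dv) / scale < tol * check_every:
                return flow
            prev = flow.copy()
    raise FlowSolverError(
        f"steady march did not converge within {max_iter} steps "
        f"(last relative change {max(du, dv) / scale:.3e})"
    )
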