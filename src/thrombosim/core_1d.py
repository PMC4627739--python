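"""One-dimensional spatial adsorption model of platelet aggregate growth.

The aggregate is described by a single dimensionless concentration profile
``C(x, t)`` in ``[0, c_max]`` growing away from a substrate (the injured
wall or the stable core of a thrombus) at the left end of the domain.  The
growth law combines a volumetric binding-site term ``C / lambda`` (side
planes of already-attached particles, ``lambda`` being the particle size)
and a surface term ``|dC/dx|`` (free column ends that seed new layers),
throttled by the saturation factor ``(1 - C/c_max)``:

    dC/dt = k_eff * (1 - C/c_max) * (C/lambda + |dC/dx|)      (variant "full")

Two classical reductions are provided: a single-binding-site,
BET-like variant that keeps only the gradient term,

    dC/dt = k_eff * (1 - C/c_max) * |dC/dx|                   (variant "bet")

and the Rosen model without binding-site saturation, which is pure
advection at speed ``k_eff``:

    dC/dt = -k_eff * dC/dx                                    (variant "rosen")

There is no diffusion term; the front nevertheless travels as a wave of
fixed shape whose speed is measured by the growth rate of the integral
``d/dt \\int C dx``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "VARIANTS",
    "AdsorptionParams1D",
    "Grid1D",
    "ConcentrationField1D",
    "Trajectory1D",
    "FieldAboveLevelError",
    "FieldBelowLevelError",
    "rhs_1d",
    "max_stable_dt_1d",
    "step_1d",
    "simulate_1d",
    "wave_velocity_1d",
    "front_position",
    "front_steepness",
    "optimal_translate_gap",
]

VARIANTS = ("full", "bet", "rosen")

#: CFL-type safety factor used when a time step is chosen automatically.
DEFAULT_SAFETY = 0.5


class FieldAboveLevelError(ValueError):
    """The profile lies entirely above the requested level."""


class FieldBelowLevelError(ValueError):
    """The profile lies entirely below the requested level."""


@dataclass(frozen=True)
class AdsorptionParams1D:
    """Physical parameters of the 1D adsorption equation.

    Parameters
    ----------
    lambda_len : float
        Characteristic particle (platelet) size, m.  Sets the strength of
        the volumetric ``C/lambda`` attachment term.
    k_eff : float
        Apparent adhesion efficiency, m/s.  Absorbs hematocrit, shear rate
        and the free-platelet concentration near the aggregate.
    c_max : float
        Maximum (close-packing) concentration; 1 in dimensionless form.
    variant : {"full", "bet", "rosen"}
        Which member of the model family to integrate.
    """

    lambda_len: float = 1e-6
    k_eff: float = 5e-7
    c_max: float = 1.0
    variant: str = "full"

    def __post_init__(self) -> None:
        if not (self.lambda_len > 0):
            raise ValueError(f"lambda_len must be > 0, got {self.lambda_len}")
        if not (self.k_eff > 0):
            raise ValueError(f"k_eff must be > 0, got {self.k_eff}")
        if not (self.c_max > 0):
            raise ValueError(f"c_max must be > 0, got {self.c_max}")
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1D grid: ``n_cells`` values at nodes ``x_i = i * dx``."""

    length: float = 1e-4
    n_cells: int = 200

    def __post_init__(self) -> None:
        if not (self.length > 0):
            raise ValueError(f"length must be > 0, got {self.length}")
        if self.n_cells < 2:
            raise ValueError(f"n_cells must be >= 2, got {self.n_cells}")

    @property
    def dx(self) -> float:
        return self.length / self.n_cells

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.n_cells) * self.dx


@dataclass
class ConcentrationField1D:
    """A concentration profile on a :class:`Grid1D` at a given time."""

    grid: Grid1D
    values: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_cells,):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_cells},)"
            )

    def copy(self) -> "ConcentrationField1D":
        return ConcentrationField1D(self.grid, self.values.copy(), self.time)

    def integral(self) -> float:
        """Discrete ``\\int C dx`` (rectangle rule)."""
        return float(self.values.sum() * self.grid.dx)

    @classmethod
    def substrate_seed(
        cls, grid: Grid1D, c_max: float = 1.0, seed_cells: int = 1
    ) -> "ConcentrationField1D":
        """Substrate initial condition: ``C = c_max`` on the leftmost
        ``seed_cells`` nodes, zero elsewhere."""
        values = np.zeros(grid.n_cells)
        values[:seed_cells] = c_max
        return cls(grid, values)


@dataclass
class Trajectory1D:
    """Recorded snapshots of a 1D run plus diagnostics flags."""

    snapshots: list[ConcentrationField1D]
    params: AdsorptionParams1D
    #: True if the front contacted the right boundary during the run
    #: (velocity measurements past that point are invalid).
    boundary_contact: bool = False
    boundary_contact_time: float | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])


def _check_field(field: ConcentrationField1D) -> None:
    if not np.all(np.isfinite(field.values)):
        raise ValueError("concentration field contains non-finite values")


def _backward_gradient(values: np.ndarray, dx: float) -> np.ndarray:
    """Substrate-side one-sided difference ``(C_i - C_{i-1}) / dx``.

    This is the Godunov upwind choice for the gradient-magnitude term of a
    front that propagates away from the high-concentration (substrate)
    side.  The substrate node uses a zero ghost gradient.
    """
    grad = np.zeros_like(values)
    grad[1:] = (values[1:] - values[:-1]) / dx
    return grad


def rhs_1d(
    field: ConcentrationField1D, params: AdsorptionParams1D
) -> np.ndarray:
    """Discrete right-hand side (1/s per node) of the selected variant."""
    _check_field(field)
    c = field.values
    dx = field.grid.dx
    grad = _backward_gradient(c, dx)
    if params.variant == "full":
        return params.k_eff * (1.0 - c / params.c_max) * (
            c / params.lambda_len + np.abs(grad)
        )
    if params.variant == "bet":
        return params.k_eff * (1.0 - c / params.c_max) * np.abs(grad)
    if params.variant == "rosen":
        # pure advection at speed k_eff, upwinded from the substrate side
        return -params.k_eff * grad
    raise ValueError(f"unknown variant {params.variant!r}")  # pragma: no cover


def max_stable_dt_1d(
    grid: Grid1D, params: AdsorptionParams1D, safety: float = DEFAULT_SAFETY
) -> float:
    """CFL-type stability bound ``safety * dx / (k_eff * (1 + dx/lambda))``."""
    dx = grid.dx
    return safety * dx / (params.k_eff * (1.0 + dx / params.lambda_len))


def step_1d(
    field: ConcentrationField1D,
    params: AdsorptionParams1D,
    dt: float,
) -> ConcentrationField1D:
    """One forward-Euler step.

    The leftmost node is a Dirichlet substrate (held fixed); the result is
    clipped to ``[0, c_max]`` to preserve the model's hard bounds against
    the O(dt^2) overshoot of explicit Euler.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    # The bound below uses safety factor 1 (the hard limit); callers pick
    # their own safety margin via max_stable_dt_1d.
    hard = max_stable_dt_1d(field.grid, params, safety=1.0)
    if dt > hard * (1 + 1e-12):
        raise ValueError(
            f"dt = {dt:g} s violates the stability bound {hard:g} s "
            f"(dx = {field.grid.dx:g} m)"
        )
    rate = rhs_1d(field, params)
    new = field.values + dt * rate
    new[0] = field.values[0]  # Dirichlet substrate
    np.clip(new, 0.0, params.c_max, out=new)
    return ConcentrationField1D(field.grid, new, field.time + dt)


def simulate_1d(
    initial: ConcentrationField1D,
    params: AdsorptionParams1D,
    t_end: float,
    dt: float | None = None,
    record_every: float | None = None,
    safety: float = DEFAULT_SAFETY,
) -> Trajectory1D:
    """Integrate the 1D model to ``t_end``, recording snapshots.

    Parameters
    ----------
    dt : float, optional
        Time step; defaults to the stability bound with ``safety``.
    record_every : float, optional
        Recording cadence (snapped to the nearest whole step); defaults to
        10 snapshots over the run.
    """
    if t_end < 0:
        raise ValueError(f"t_end must be >= 0, got {t_end}")
    if t_end == 0:
        return Trajectory1D([initial.copy()], params)
    if dt is None:
        dt = max_stable_dt_1d(initial.grid, params, safety=safety)
    n_steps = max(1, int(round(t_end / dt)))
    if record_every is None:
        record_stride = max(1, n_steps // 10)
    else:
        record_stride = max(1, int(round(record_every / dt)))

    field = initial.copy()
    snapshots = [field.copy()]
    contact = False
    contact_time = None
    threshold = 0.01 * params.c_max
    for k in range(1, n_steps + 1):
        field = step_1d(field, params, dt)
        if not contact and field.values[-1] > threshold:
            contact = True
            contact_time = field.time
        if k % record_stride == 0 or k == n_steps:
            snapshots.append(field.copy())
    return Trajectory1D(snapshots, params, contact, contact_time)


def wave_velocity_1d(
    trajectory: Trajectory1D,
    boundary_margin_cells: int = 10,
    front_level: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Front velocity from the growth of the profile integral.

    The velocity at each interior snapshot is the central difference in
    time of the discrete ``\\int C dx``.  The plateau value is the mean
    over the last third of the valid series, where a snapshot is valid if
    the front is at least ``boundary_margin_cells`` nodes from the right
    boundary.

    Returns
    -------
    times, velocities : ndarray
        Interior snapshot times and the velocity series, m/s.
    plateau : float
        Late-time mean velocity, m/s.
    """
    snaps = trajectory.snapshots
    if len(snaps) < 3:
        raise ValueError(f"need >= 3 snapshots, got {len(snaps)}")
    times = trajectory.times
    integrals = np.array([s.integral() for s in snaps])
    vel = (integrals[2:] - integrals[:-2]) / (times[2:] - times[:-2])
    vel_times = times[1:-1]

    grid = snaps[0].grid
    params = trajectory.params
    limit = grid.length - boundary_margin_cells * grid.dx
    valid = []
    for snap, v in zip(snaps[1:-1], vel):
        try:
            pos = front_position(snap, level=front_level, c_max=params.c_max)
        except FieldBelowLevelError:
            pos = 0.0
        except FieldAboveLevelError:
            pos = grid.length
        if pos <= limit:
            valid.append(v)
    if not valid:
        raise ValueError(
            "no snapshot keeps the front clear of the right boundary; "
            "shorten the run or enlarge the domain"
        )
    tail = valid[max(0, len(valid) - max(1, len(valid) // 3)):]
    plateau = float(np.mean(tail))
    return vel_times, vel, plateau


def front_position(
    field: ConcentrationField1D, level: float = 0.5, c_max: float = 1.0
) -> float:
    """Position (m) of the first downcrossing of ``level * c_max``.

    Scans from the substrate and linearly interpolates between the nodes
    bracketing the crossing.
    """
    c = field.values
    lev = level * c_max
    if np.all(c >= lev):
        raise FieldAboveLevelError(f"field never drops below level {lev}")
    if np.all(c < lev):
        raise FieldBelowLevelError(f"field never reaches level {lev}")
    above = c >= lev
    # first index where an above-level node is followed by a below-level node
    idx = np.nonzero(above[:-1] & ~above[1:])[0]
    if idx.size == 0:
        raise FieldBelowLevelError(
            f"no downcrossing of level {lev} found (profile not monotone?)"
        )
    i = int(idx[0])
    dx = field.grid.dx
    x0 = i * dx
    c0, c1 = c[i], c[i + 1]
    return float(x0 + dx * (c0 - lev) / (c0 - c1))


def front_steepness(
    field: ConcentrationField1D, c_max: float = 1.0
) -> tuple[float, float]:
    """Front width and maximum slope.

    Returns
    -------
    width : float
        Distance (m) between the interpolated 0.9*c_max and 0.1*c_max
        downcrossings.
    max_slope : float
        Maximum backward-difference magnitude, 1/m.
    """
    hi = front_position(field, level=0.9, c_max=c_max)
    lo = front_position(field, level=0.1, c_max=c_max)
    width = lo - hi
    grad = _backward_gradient(field.values, field.grid.dx)
    max_slope = float(np.abs(grad).max())
    return float(width), max_slope


def optimal_translate_gap(
    a: ConcentrationField1D,
    b: ConcentrationField1D,
    c_max: float = 1.0,
    margin_cells: int = 5,
) -> float:
    """Max-norm gap between two profiles after the optimal translation.

    Measures how well two snapshots of a traveling wave are translates of
    one another: profile ``b`` is shifted back by the front-position
    difference (refined by a bounded 1D minimization), linearly
    interpolated onto the grid of ``a``, and compared on the overlap away
    from the domain ends.
    """
    from scipy.optimize import minimize_scalar

    grid = a.grid
    x = grid.x
    shift0 = front_position(b, c_max=c_max) - front_position(a, c_max=c_max)

    def gap(shift: float) -> float:
        xs = x + shift
        inside = (
            (xs >= margin_cells * grid.dx)
            & (xs <= grid.length - margin_cells * grid.dx)
            & (x >= margin_cells * grid.dx)
        )
        if not inside.any():
            return np.inf
        bs = np.interp(xs[inside], x, b.values)
        return float(np.abs(a.values[inside] - bs).max())

    res = minimize_scalar(
        gap, bounds=(shift0 - 2 * grid.dx, shift0 + 2 * grid.dx),
        method="bounded", options={"xatol": grid.dx * 1e-4},
    )
    return float(min(res.fun, gap(shift0)))
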