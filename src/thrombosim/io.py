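"""Field and metric output: CSV grids and legacy-VTK structured grids.

CSV fields are written row-major (one row per x index, columns along y)
under a comment header naming the axes, spacings and units, so a file is
self-describing and rewrites are bit-identical for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from thrombosim.core_1d import Trajectory1D
from thrombosim.flow_2d import ChannelGrid2D, FlowField, divergence, shear_rate_field

__all__ = [
    "write_field_csv",
    "read_field_csv",
    "write_field",
    "write_flow_vtk",
    "write_trajectory_1d_csv",
    "write_metrics_csv",
    "write_manifest",
]

_HEADER = (
    "# thrombosim field: {name}\n"
    "# origin: inlet/bottom-wall corner; x along the flow, y across\n"
    "# rows: x index (dx = {dx:.9g} m); columns: y index (dy = {dy:.9g} m)\n"
    "# units: {units}; time: {time:.9g} s\n"
)


def write_field_csv(
    field: np.ndarray,
    path: str | Path,
    name: str = "field",
    dx: float = 1.0,
    dy: float = 1.0,
    units: str = "dimensionless",
    time: float = 0.0,
) -> Path:
    """Write a 2D array as a headed CSV grid."""
    field = np.asarray(field)
    if field.ndim != 2:
        raise ValueError("write_field_csv expects a 2D array")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_HEADER.format(name=name, dx=dx, dy=dy, units=units, time=time))
        np.savetxt(fh, field, delimiter=",", fmt="%.17g")
    return path


def read_field_csv(path: str | Path) -> np.ndarray:
    """Read a grid written by :func:`write_field_csv`."""
    return np.atleast_2d(np.loadtxt(path, delimiter=",", comments="#"))


def write_field(
    field: np.ndarray,
    path: str | Path,
    fmt: str = "csv",
    **kwargs,
) -> Path:
    """Write a scalar field in the requested format (``csv`` or ``vtk``)."""
    if fmt == "csv":
        return write_field_csv(field, path, **kwargs)
    if fmt == "vtk":
        return _write_scalar_vtk(field, path, **kwargs)
    raise ValueError(f"unknown field format {fmt!r}")


def _vtk_header(fh, title: str, nx: int, ny: int, dx: float, dy: float) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")
    fh.write("DATASET STRUCTURED_POINTS\n")
    fh.write(f"DIMENSIONS {nx} {ny} 1\n")
    fh.write(f"ORIGIN {dx / 2:.9g} {dy / 2:.9g} 0\n")
    fh.write(f"SPACING {dx:.9g} {dy:.9g} 1\n")
    fh.write(f"POINT_DATA {nx * ny}\n")


def _write_array(fh, name: str, values: np.ndarray) -> None:
    fh.write(f"SCALARS {name} double 1\n")
    fh.write("LOOKUP_TABLE default\n")
    # VTK expects x fastest; our arrays are (nx, ny)
    for val in values.T.reshape(-1):
        fh.write(f"{val:.9g}\n")


def _write_scalar_vtk(
    field: np.ndarray,
    path: str | Path,
    name: str = "field",
    dx: float = 1.0,
    dy: float = 1.0,
    **_: object,
) -> Path:
    field = np.asarray(field)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx, ny = field.shape
    with open(path, "w") as fh:
        _vtk_header(fh, f"thrombosim {name}", nx, ny, dx, dy)
        _write_array(fh, name, field)
    return path


def write_flow_vtk(flow: FlowField, path: str | Path) -> Path:
    """Legacy-VTK structured-points dump of a flow state: cell-centered
    u, v, p, shear rate gamma and divergence."""
    g = flow.grid
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    uc, vc = flow.cell_center_velocity()
    with open(path, "w") as fh:
        _vtk_header(fh, "thrombosim flow", g.nx, g.ny, g.dx, g.dy)
        _write_array(fh, "u", uc)
        _write_array(fh, "v", vc)
        _write_array(fh, "p", flow.p)
        _write_array(fh, "gamma", shear_rate_field(flow))
        _write_array(fh, "divergence", divergence(flow))
    return path


def write_trajectory_1d_csv(traj: Trajectory1D, path: str | Path) -> Path:
    """1D trajectory as CSV: column ``time`` then one column per node."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    grid = traj.snapshots[0].grid
    cols = [f"x_{i}" for i in range(grid.n_cells)]
    df = pd.DataFrame(
        [s.values for s in traj.snapshots], columns=cols
    )
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def write_metrics_csv(frames, path: str | Path) -> Path:
    """Concatenate tidy metric frames (run_id, metric, time, value)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(list(frames), ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def write_manifest(path: str | Path, **entries) -> Path:
    """JSON run manifest (config echo, step counts, refresh events...)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
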