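"""Quantitative diagnostics of thrombus growth runs.

The growth speed of the 2D aggregate is measured, as in the 1D model, by
the rate of change of a concentration integral: here the y-integral of
``C`` along the cross section through the injury midpoint ``l*``.  Shape
descriptors (area, upstream/downstream extents, height) operationalize
the torch-like morphology; "the thrombus" always means the obstacle-level
set ``C >= c_b``, since that is the region the flow actually feels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from thrombosim.flow_2d import ChannelGrid2D
from thrombosim.thrombus_2d import CoupledTrajectory

__all__ = [
    "MetricsSeries",
    "cross_section_velocity",
    "thrombus_area",
    "thrombus_extents",
]


@dataclass
class MetricsSeries:
    """A named, time-stamped metric series."""

    name: str
    times: np.ndarray
    values: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self, run_id: str = "run") -> pd.DataFrame:
        """Tidy representation (run_id, metric, time, value)."""
        return pd.DataFrame(
            {
                "run_id": run_id,
                "metric": self.name,
                "time": self.times,
                "value": self.values,
            }
        )


def cross_section_velocity(
    trajectory: CoupledTrajectory, l_star: float | None = None
) -> MetricsSeries:
    """Growth velocity (m/s) of the cross-section concentration integral.

    Central difference in time of the discrete ``\\int_0^M C dy`` along
    the cell column nearest ``l_star`` (default: the trajectory's injury
    midpoint).
    """
    snaps = trajectory.snapshots
    if len(snaps) < 3:
        raise ValueError(f"need >= 3 snapshots, got {len(snaps)}")
    grid = trajectory.grid
    if l_star is None:
        l_star = trajectory.injury_center
    if not (0.0 <= l_star <= grid.length):
        raise ValueError(
            f"l_star = {l_star:g} m outside the domain [0, {grid.length:g}]"
        )
    col = int(np.clip(round(l_star / grid.dx - 0.5), 0, grid.nx - 1))
    times = trajectory.times
    integrals = np.array(
        [s.concentration[col, :].sum() * grid.dy for s in snaps]
    )
    vel = (integrals[2:] - integrals[:-2]) / (times[2:] - times[:-2])
    return MetricsSeries(
        "cross_section_velocity",
        times[1:-1],
        vel,
        params={"l_star": l_star, "column": col},
    )


def thrombus_area(c: np.ndarray, c_b: float, grid: ChannelGrid2D) -> float:
    """Obstacle area (m^2): cells at or above the threshold times the
    cell area."""
    return float(np.count_nonzero(np.asarray(c) >= c_b) * grid.dx * grid.dy)


def thrombus_extents(
    c: np.ndarray, c_b: float, injury_center: float, grid: ChannelGrid2D
) -> tuple[float, float, float]:
    """Upstream extent, downstream extent and height (m) of the obstacle.

    Extents are measured from the injury midpoint to the farthest
    obstacle-cell center against/with the flow; height is the top edge of
    the highest obstacle cell above wall D.
    """
    cells = np.asarray(c) >= c_b
    if not cells.any():
        raise ValueError("no cell reaches the obstacle threshold")
    ii, jj = np.nonzero(cells)
    x = (ii + 0.5) * grid.dx
    upstream = max(0.0, injury_center - float(x.min()))
    downstream = max(0.0, float(x.max()) - injury_center)
    height = float((jj.max() + 1) * grid.dy)
    return upstream, downstream, height
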