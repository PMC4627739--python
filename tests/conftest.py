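"""Shared fixtures.

The coupled 2D growth runs are expensive relative to everything else, so
the canonical study runs (torch-shape regime, its convectionless
companion, the two boundary-condition drivings and the two injury sizes)
are computed once per session on a half-resolution channel
(75 x 25 cells, dx = dy = 2 µm) and shared by the behavioral and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from thrombosim.core_1d import (
    AdsorptionParams1D,
    ConcentrationField1D,
    Grid1D,
    simulate_1d,
)
from thrombosim.flow_2d import ChannelGrid2D, FlowBC, FluidParams
from thrombosim.thrombus_2d import InjurySpec, ThrombusParams, simulate_coupled

#: horizon (s) of the reduced torch-shape runs
TORCH_T_END = 200.0
#: horizon (s) of the boundary-condition contrast runs (kept short of
#: full occlusion, where the fixed-flux problem ceases to exist)
BC_CONTRAST_T_END = 450.0
#: horizon (s) of the injury-size comparison
INJURY_T_END = 500.0


@pytest.fixture(scope="session")
def fluid():
    return FluidParams()


@pytest.fixture(scope="session")
def reduced_grid():
    """Half-resolution channel: 150 x 50 µm at dx = dy = 2 µm."""
    return ChannelGrid2D(nx=75, ny=25)


@pytest.fixture(scope="session")
def thrombus_defaults():
    return ThrombusParams()


def run_coupled(grid, fluid, bc, params, injury, t_end, record_every=None):
    return simulate_coupled(
        grid, fluid, bc, params, injury,
        t_end=t_end,
        record_every=record_every or t_end / 12,
        n_refresh=50,
    )


@pytest.fixture(scope="session")
def torch_run(reduced_grid, fluid, thrombus_defaults):
    """Reference growth regime: pressure-gradient BC, default coefficients."""
    return run_coupled(
        reduced_grid, fluid, FlowBC(), thrombus_defaults, InjurySpec(),
        TORCH_T_END,
    )


@pytest.fixture(scope="session")
def no_movability_run(reduced_grid, fluid):
    """Companion run with k_rol = 0 (no convective platelet transport)."""
    return run_coupled(
        reduced_grid, fluid, FlowBC(), ThrombusParams(k_rol=0.0),
        InjurySpec(), TORCH_T_END,
    )


@pytest.fixture(scope="session")
def bc_contrast_runs(reduced_grid, fluid, thrombus_defaults):
    """The same growth problem under both inlet/outlet drivings."""
    runs = {}
    for name, bc in [
        ("pressure_gradient", FlowBC()),
        ("velocity_profile", FlowBC(variant="velocity_profile")),
    ]:
        runs[name] = run_coupled(
            reduced_grid, fluid, bc, thrombus_defaults, InjurySpec(),
            BC_CONTRAST_T_END, record_every=25.0,
        )
    return runs


@pytest.fixture(scope="session")
def injury_size_runs(reduced_grid, fluid, thrombus_defaults):
    """Reference injury (15 µm) vs a 10-fold smaller one (1.5 µm)."""
    runs = {}
    for name, l0 in [("large", 15e-6), ("small", 1.5e-6)]:
        runs[name] = run_coupled(
            reduced_grid, fluid, FlowBC(), thrombus_defaults,
            InjurySpec(l0=l0), INJURY_T_END,
        )
    return runs


@pytest.fixture(scope="session")
def traveling_wave_run():
    """Late-time 1D front at the reference parameters (λ = 1 µm,
    k_eff = 5e-7 m/s)."""
    grid = Grid1D(1e-4, 200)
    params = AdsorptionParams1D(variant="full", lambda_len=1e-6, k_eff=5e-7)
    initial = ConcentrationField1D.substrate_seed(grid)
    return simulate_1d(initial, params, t_end=50.0, record_every=5.0)
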