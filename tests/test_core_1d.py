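"""Unit and property tests of the 1D spatial adsorption model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thrombosim.core_1d import (
    AdsorptionParams1D,
    ConcentrationField1D,
    FieldAboveLevelError,
    FieldBelowLevelError,
    Grid1D,
    Trajectory1D,
    front_position,
    front_steepness,
    max_stable_dt_1d,
    optimal_translate_gap,
    rhs_1d,
    simulate_1d,
    step_1d,
    wave_velocity_1d,
)


def make_field(values, dx=1e-6):
    values = np.asarray(values, dtype=float)
    return ConcentrationField1D(Grid1D(dx * len(values), len(values)), values)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lambda_len": 0.0},
            {"k_eff": -1e-7},
            {"c_max": 0.0},
            {"variant": "langmuir"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AdsorptionParams1D(**kwargs)


class TestRhs:
    @pytest.mark.parametrize("variant", ["full", "bet"])
    def test_saturated_and_empty_profiles_have_zero_rate(self, variant):
        params = AdsorptionParams1D(variant=variant)
        for level in (0.0, 1.0):
            field = make_field(np.full(8, level))
            assert rhs_1d(field, params) == pytest.approx(np.zeros(8))

    def test_hand_evaluated_middle_cell(self):
        # backward-difference rule: 5e-7 * (1 - 0.5) * (0.5/1e-6 + 0.5/1e-6)
        field = make_field([1.0, 0.5, 0.0])
        params = AdsorptionParams1D(lambda_len=1e-6, k_eff=5e-7, variant="full")
        assert rhs_1d(field, params)[1] == pytest.approx(0.25)

    def test_matches_independent_stencil_evaluation(self):
        # scripted point-by-point evaluation as an independent oracle
        rng = np.random.default_rng(7)
        values = np.sort(rng.uniform(0, 1, 32))[::-1].copy()
        field = make_field(values, dx=2e-6)
        params = AdsorptionParams1D(lambda_len=3e-6, k_eff=2e-7, variant="full")
        expected = np.zeros_like(values)
        dx = field.grid.dx
        for i in range(len(values)):
            grad = 0.0 if i == 0 else (values[i] - values[i - 1]) / dx
            expected[i] = (
                params.k_eff
                * (1 - values[i] / params.c_max)
                * (values[i] / params.lambda_len + abs(grad))
            )
        assert rhs_1d(field, params) == pytest.approx(expected)

    def test_rosen_is_upwind_advection(self):
        field = make_field([1.0, 0.5, 0.0])
        params = AdsorptionParams1D(variant="rosen", k_eff=5e-7)
        rate = rhs_1d(field, params)
        assert rate[1] == pytest.approx(5e-7 * 0.5 / 1e-6)

    def test_non_finite_field_rejected(self):
        field = make_field([1.0, np.nan, 0.0])
        with pytest.raises(ValueError, match="non-finite"):
            rhs_1d(field, AdsorptionParams1D())


class TestStep:
    def test_substrate_seed_only_spreads_one_cell(self):
        grid = Grid1D(1e-5, 10)
        field = ConcentrationField1D.substrate_seed(grid)
        params = AdsorptionParams1D()
        dt = max_stable_dt_1d(grid, params)
        new = step_1d(field, params, dt)
        assert new.values[1] > 0
        assert new.values[2:] == pytest.approx(np.zeros(8))
        assert new.values[0] == 1.0  # Dirichlet substrate

    def test_saturated_profile_is_stationary(self):
        field = make_field(np.ones(6))
        params = AdsorptionParams1D()
        new = step_1d(field, params, max_stable_dt_1d(field.grid, params))
        assert new.values == pytest.approx(field.values)

    def test_rosen_integral_grows_exactly_linearly(self):
        # telescoping upwind flux: d(int C dx)/dt = k_eff * (C_left - C_right)
        grid = Grid1D(1e-4, 100)
        field = ConcentrationField1D.substrate_seed(grid, seed_cells=10)
        params = AdsorptionParams1D(variant="rosen")
        dt = 0.5
        n_steps = 40
        before = field.integral()
        for _ in range(n_steps):
            field = step_1d(field, params, dt)
        gained = field.integral() - before
        assert gained == pytest.approx(params.k_eff * dt * n_steps, rel=1e-12)

    @pytest.mark.parametrize("dt", [0.0, -1.0, 10.0])
    def test_invalid_dt_rejected(self, dt):
        field = make_field(np.linspace(1, 0, 8))
        with pytest.raises(ValueError):
            step_1d(field, AdsorptionParams1D(), dt)

    @settings(deadline=None, max_examples=25)
    @given(
        data=st.lists(st.floats(0.0, 1.0), min_size=4, max_size=24),
        variant=st.sampled_from(["full", "bet"]),
    )
    def test_bounds_and_monotone_growth(self, data, variant):
        """Irreversible attachment: values stay in [0, c_max] and never
        decrease under stable stepping."""
        values = np.array([1.0] + data)
        field = make_field(values)
        params = AdsorptionParams1D(variant=variant)
        dt = max_stable_dt_1d(field.grid, params)
        for _ in range(5):
            new = step_1d(field, params, dt)
            assert np.all(new.values >= field.values - 1e-15)
            assert np.all(new.values >= 0) and np.all(new.values <= 1)
            field = new


class TestSimulate:
    def test_zero_horizon_returns_initial_only(self):
        grid = Grid1D(1e-5, 10)
        initial = ConcentrationField1D.substrate_seed(grid)
        traj = simulate_1d(initial, AdsorptionParams1D(), t_end=0.0)
        assert len(traj.snapshots) == 1
        assert traj.snapshots[0].values == pytest.approx(initial.values)

    def test_rosen_transports_smooth_profile_at_k_eff(self):
        # pure advection: the profile at time T approximates the initial
        # one shifted by k_eff * T (first-order scheme -> loose tolerance
        # on a fine grid)
        grid = Grid1D(1e-4, 2000)
        x = grid.x
        initial = ConcentrationField1D(
            grid, 1.0 / (1.0 + np.exp((x - 2e-5) / 2e-6))
        )
        params = AdsorptionParams1D(variant="rosen", k_eff=5e-7)
        t_end = 40.0
        traj = simulate_1d(initial, params, t_end=t_end, record_every=t_end)
        final = traj.snapshots[-1]
        shifted = np.interp(x - params.k_eff * t_end, x, initial.values)
        interior = x > 5e-6
        assert np.abs(final.values - shifted)[interior].max() < 0.06

    def test_boundary_contact_flagged(self):
        grid = Grid1D(1e-5, 10)  # tiny domain: front hits the end quickly
        initial = ConcentrationField1D.substrate_seed(grid)
        traj = simulate_1d(initial, AdsorptionParams1D(), t_end=60.0)
        assert traj.boundary_contact
        assert traj.boundary_contact_time is not None


class TestWaveVelocity:
    def test_stationary_trajectory_has_zero_velocity(self):
        field = make_field(np.linspace(1, 0, 20))
        snaps = []
        for t in (0.0, 1.0, 2.0, 3.0):
            s = field.copy()
            s.time = t
            snaps.append(s)
        traj = Trajectory1D(snaps, AdsorptionParams1D())
        _, vel, plateau = wave_velocity_1d(traj)
        assert vel == pytest.approx(np.zeros(2))
        assert plateau == 0.0

    def test_requires_three_snapshots(self):
        field = make_field(np.linspace(1, 0, 20))
        with pytest.raises(ValueError, match="3 snapshots"):
            wave_velocity_1d(Trajectory1D([field, field], AdsorptionParams1D()))

    def test_rosen_plateau_equals_k_eff(self):
        grid = Grid1D(1e-4, 200)
        params = AdsorptionParams1D(variant="rosen")
        initial = ConcentrationField1D.substrate_seed(grid)
        traj = simulate_1d(initial, params, t_end=60.0)
        _, _, plateau = wave_velocity_1d(traj)
        assert plateau == pytest.approx(params.k_eff, rel=1e-9)

    def test_front_position_estimator_agrees_with_integral_estimator(
        self, traveling_wave_run
    ):
        traj = traveling_wave_run
        _, _, plateau = wave_velocity_1d(traj)
        a, b = traj.snapshots[-4], traj.snapshots[-1]
        v_front = (front_position(b) - front_position(a)) / (b.time - a.time)
        assert v_front == pytest.approx(plateau, rel=0.05)

    def test_doubling_k_eff_doubles_plateau_velocity(self, traveling_wave_run):
        _, _, v1 = wave_velocity_1d(traveling_wave_run)
        grid = Grid1D(1e-4, 200)
        params = AdsorptionParams1D(variant="full", lambda_len=1e-6, k_eff=1e-6)
        initial = ConcentrationField1D.substrate_seed(grid)
        traj = simulate_1d(initial, params, t_end=25.0, record_every=2.5)
        _, _, v2 = wave_velocity_1d(traj)
        assert v2 / v1 == pytest.approx(2.0, rel=0.02)


class TestFrontDiagnostics:
    def test_midpoint_interpolation(self):
        field = make_field([1.0, 1.0, 0.0, 0.0])
        assert front_position(field, level=0.5) == pytest.approx(1.5e-6)

    def test_distinct_errors_above_and_below(self):
        with pytest.raises(FieldBelowLevelError):
            front_position(make_field(np.zeros(5)))
        with pytest.raises(FieldAboveLevelError):
            front_position(make_field(np.ones(5)))

    def test_step_profile_width_at_most_one_cell(self):
        field = make_field([1, 1, 1, 0, 0, 0])
        width, slope = front_steepness(field)
        assert width <= field.grid.dx + 1e-18
        assert slope == pytest.approx(1.0 / field.grid.dx)

    def test_linear_ramp_width_spans_eight_cells(self):
        values = np.concatenate([np.linspace(1, 0, 11), np.zeros(4)])
        field = make_field(values)
        width, _ = front_steepness(field)
        assert width == pytest.approx(8 * field.grid.dx)

    def test_missing_crossings_rejected(self):
        with pytest.raises(FieldBelowLevelError):
            front_steepness(make_field(np.full(6, 0.05)))


class TestModelFamily:
    def test_full_converges_to_bet_as_lambda_grows(self):
        """With the volumetric C/λ term fading, the full model approaches
        the single-site (gradient-only) variant monotonically."""
        grid = Grid1D(1e-4, 100)
        initial = ConcentrationField1D.substrate_seed(grid)
        k_eff = 5e-7
        dt = 0.4 * grid.dx / (k_eff * (1 + grid.dx / 1e-5))
        t_end = 40.0
        bet = simulate_1d(
            initial, AdsorptionParams1D(variant="bet", k_eff=k_eff),
            t_end=t_end, dt=dt, record_every=t_end,
        ).snapshots[-1]
        gaps = []
        for lam in (1e-5, 1e-4, 1e-3):
            full = simulate_1d(
                initial,
                AdsorptionParams1D(variant="full", lambda_len=lam, k_eff=k_eff),
                t_end=t_end, dt=dt, record_every=t_end,
            ).snapshots[-1]
            gaps.append(np.abs(full.values - bet.values).max())
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[-1] < 0.02

    def test_front_speed_decreases_toward_k_eff_under_refinement(self):
        """Without diffusion the discrete front width is grid-set, so the
        selected speed exceeds k_eff by an O(dx/λ) margin that shrinks
        monotonically under refinement."""
        k_eff = 5e-7
        speeds = []
        for n in (50, 100, 200):
            grid = Grid1D(1e-4, n)
            initial = ConcentrationField1D.substrate_seed(grid)
            traj = simulate_1d(
                initial,
                AdsorptionParams1D(variant="full", lambda_len=1e-6, k_eff=k_eff),
                t_end=50.0, record_every=5.0,
            )
            _, _, plateau = wave_velocity_1d(traj)
            speeds.append(plateau)
        assert speeds[0] > speeds[1] > speeds[2]
        assert all(v >= k_eff for v in speeds)

    def test_width_grows_and_slope_falls_with_lambda(self):
        """Larger particles smear the front: the 0.1–0.9 transition zone
        widens and the maximum slope drops as λ grows."""
        grid = Grid1D(1e-4, 200)
        initial = ConcentrationField1D.substrate_seed(grid)
        widths, slopes = [], []
        for lam in (1e-6, 2e-6, 3e-6):
            traj = simulate_1d(
                initial,
                AdsorptionParams1D(variant="full", lambda_len=lam, k_eff=5e-7),
                t_end=30.0, record_every=5.0,
            )
            width, slope = front_steepness(traj.snapshots[-1])
            widths.append(width)
            slopes.append(slope)
        assert widths[0] < widths[1] < widths[2]
        assert slopes[0] > slopes[1] > slopes[2]

    def test_late_profiles_are_translates(self, traveling_wave_run):
        snaps = traveling_wave_run.snapshots
        gap = optimal_translate_gap(snaps[-3], snaps[-1])
        assert gap < 0.02
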