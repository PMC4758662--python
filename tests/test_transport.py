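"""Moving-boundary transport: velocity, conservation, growth regimes."""

import numpy as np
import pytest

from pelletgrowth import (
    ModelParameters,
    RadialGrid,
    SolverConfig,
    advance,
    compute_velocity,
    initial_state,
    run_to,
    trajectory_to_dataframe,
    validate_state,
)
from pelletgrowth.transport import cell_volume_integral


class TestComputeVelocity:
    def test_no_production_no_flow(self, grid200):
        v = compute_velocity(np.zeros(200), np.ones(200), 2.0, 0.3, grid200)
        assert np.allclose(v, 0.0)

    def test_saturated_linear_velocity(self, grid200):
        # f*n ~ 1 everywhere gives v(r) = r/3; surface speed 2/3 at S=2
        S = 2.0
        v = compute_velocity(np.ones(200), np.ones(200), S, 1e-9, grid200)
        expected = grid200.y * S / 3.0
        assert np.max(np.abs(v - expected)) < 1e-6
        assert v[-1] == pytest.approx(2.0 / 3.0, rel=1e-6)

    def test_idealized_dead_core_velocity(self):
        # production only outside r = a: v = (r^3 - a^3)/(3 r^2)
        grid = RadialGrid(401)
        S, a_frac = 2.0, 0.5
        n = (grid.y > a_frac).astype(float)
        v = compute_velocity(np.ones(401), n, S, 1e-9, grid)
        r = grid.y * S
        a = a_frac * S
        expected = np.where(r > a, (r**3 - a**3) / (3 * np.maximum(r, 1e-30) ** 2), 0.0)
        # first-order accuracy at the jump; fine elsewhere
        assert np.max(np.abs(v - expected)) < 2 * S * grid.dy

    def test_nonnegative_and_zero_at_centre(self, grid200):
        rng = np.random.default_rng(0)
        B = np.sort(rng.uniform(0, 1, 200))
        n = rng.uniform(0, 1, 200)
        v = compute_velocity(B, n, 3.0, 0.3, grid200)
        assert v[0] == 0.0
        assert np.all(v >= 0)


class TestAdvance:
    def test_empty_pellet_is_fixed_point(self, grid200):
        params = ModelParameters(kappa=0.3, sigma0=2.0)
        state = initial_state(params, grid200)
        state.n[:] = 0.0
        state.p[:] = 1.0
        state.B[:] = 1.0
        state.v[:] = 0.0
        new, rep = advance(state, 1e-3, params, grid200)
        assert new.S == state.S
        assert np.allclose(new.n, 0.0, atol=1e-15)
        assert rep.mass_drift == 0.0

    def test_saturated_small_step_expansion(self):
        # B ~ 1 everywhere: dn/dt = -n^2 and dS/dt = S/3 to O(dt^2)
        grid = RadialGrid(100)
        params = ModelParameters(kappa=1e-6, sigma0=1.0)
        state = initial_state(params, grid)
        dt = 1e-3
        new, rep = advance(state, dt, params, grid)
        assert np.max(np.abs(new.n - (1 - dt))) < 5 * dt**2
        assert new.S == pytest.approx(1.0 * (1 + dt / 3.0), abs=5 * dt**2)
        assert rep.S_new == new.S

    def test_hundred_step_conservation(self, grid200):
        params = ModelParameters(kappa=0.3, sigma0=2.0)
        config = SolverConfig(dt=1e-3)
        state = initial_state(params, grid200, config)
        M0 = cell_volume_integral(state.n, state.S, grid200)
        assert M0 == pytest.approx(2.0**3 / 3.0, rel=1e-4)  # Sigma0^3/3
        for _ in range(100):
            state, _ = advance(state, 1e-3, params, grid200, config)
        M = cell_volume_integral(state.n, state.S, grid200)
        assert abs(M / M0 - 1) < 1e-3

    def test_closure_is_exact(self, small_pellet_state):
        params, state = small_pellet_state
        for _ in range(20):
            state, _ = advance(state, 1e-3, params, RadialGrid(200))
        assert np.max(np.abs(state.n + state.p - 1.0)) <= 1e-10

    def test_growth_is_monotone_and_rate_bounded(self, small_pellet_state):
        params, state = small_pellet_state
        grid = RadialGrid(200)
        for _ in range(30):
            new, rep = advance(state, 1e-3, params, grid)
            assert new.S > state.S  # nutrient present at the surface
            # production factor f*n <= 1 caps the boundary speed at S/3
            assert (new.S - state.S) / rep.dt <= state.S / 3.0 + 1e-12
            state = new

    def test_step_rejection_halves_dt(self, small_pellet_state):
        params, state = small_pellet_state
        grid = RadialGrid(200)
        _, rep = advance(state, 1e-2, params, grid)
        tight = SolverConfig(dt=1e-2, step_mass_tol=abs(rep.mass_drift) / 2)
        _, rep2 = advance(state, 1e-2, params, grid, tight)
        assert rep2.dt < 1e-2
        assert abs(rep2.mass_drift) <= tight.step_mass_tol

    def test_impossible_mass_tolerance_raises(self, small_pellet_state):
        params, state = small_pellet_state
        config = SolverConfig(step_mass_tol=1e-17, max_halvings=2)
        with pytest.raises(RuntimeError, match="rejected"):
            advance(state, 1e-2, params, RadialGrid(200), config)

    def test_invalid_inputs_raise(self, small_pellet_state):
        params, state = small_pellet_state
        grid = RadialGrid(200)
        with pytest.raises(ValueError):
            advance(state, -1e-3, params, grid)
        bad = state.copy()
        bad.n[5] = 1.5
        bad.p[5] = -0.5
        with pytest.raises(ValueError, match="invalid input state"):
            advance(bad, 1e-3, params, grid)

    def test_independent_p_matches_closure(self, grid200):
        # debug-integrated p obeys its own conservation law yet agrees
        # with 1 - n to solver round-off
        params = ModelParameters(kappa=0.3, sigma0=2.0)
        config = SolverConfig(dt=2e-3, track_independent_p=True)
        state = initial_state(params, grid200, config)
        final = run_to(state, 0.4, params, grid200, config)[-1]
        assert final.p_debug is not None
        assert np.max(np.abs(final.p_debug - (1 - final.n))) < 1e-6


class TestRunTo:
    def test_zero_span_returns_unchanged_state(self, small_pellet_state):
        params, state = small_pellet_state
        out = run_to(state, state.t, params, RadialGrid(200))
        assert len(out) == 1
        assert out[0].S == state.S
        assert np.array_equal(out[0].n, state.n)

    def test_checkpoints_are_hit_and_valid(self, small_pellet_state):
        params, state = small_pellet_state
        grid = RadialGrid(200)
        cps = [0.05, 0.1, 0.2]
        out = run_to(state, 0.2, params, grid, SolverConfig(dt=3e-3), checkpoints=cps)
        assert [pytest.approx(c) for c in cps] == [s.t for s in out]
        S_values = [s.S for s in out]
        assert S_values == sorted(S_values)
        for s in out:
            assert validate_state(s, sigma0=params.sigma0) == []

    def test_bad_time_targets_raise(self, small_pellet_state):
        params, state = small_pellet_state
        grid = RadialGrid(200)
        with pytest.raises(ValueError):
            run_to(state, -1.0, params, grid)
        with pytest.raises(ValueError):
            run_to(state, 1.0, params, grid, checkpoints=[2.0])

    def test_first_order_mass_drift_in_dt(self, grid200):
        # fast-growth scenario; halving dt roughly halves the drift
        params = ModelParameters(kappa=0.005, sigma0=2.0)
        drifts = []
        for dt in (1e-3, 5e-4):
            config = SolverConfig(dt=dt)
            s0 = initial_state(params, grid200, config)
            M0 = cell_volume_integral(s0.n, s0.S, grid200)
            final = run_to(s0, 1.0, params, grid200, config)[-1]
            drifts.append(abs(cell_volume_integral(final.n, final.S, grid200) / M0 - 1))
        assert drifts[0] < 1e-3
        assert drifts[1] < 0.7 * drifts[0]


class TestTrajectoryExport:
    def test_long_format_columns_and_units(self, small_pellet_state, scales):
        params, state = small_pellet_state
        grid = RadialGrid(200)
        out = run_to(state, 0.046, params, grid, checkpoints=[0.0, 0.046])
        df = trajectory_to_dataframe(out, scales, grid)
        expected = [
            "time_model", "time_days", "y", "r_dimless", "r_um",
            "n", "p", "B", "v", "S_dimless", "S_um",
        ]
        assert list(df.columns) == expected
        assert len(df) == 2 * grid.N
        assert df["time_days"].iloc[-1] == pytest.approx(0.2)  # 0.046 / 0.23
        assert np.allclose(df["r_um"], df["r_dimless"] * scales.L_um)
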