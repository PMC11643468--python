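import numpy as np
import pytest

from swarmsteer.dynamics import (
    ACTIVE,
    EXITED,
    STUCK,
    InvalidSeedError,
    SeedSpec,
    SimConfig,
    major_step,
    minor_step,
    resolve_collision,
    run_simulation,
    seed_particles,
    semi_static_velocity,
)
from swarmsteer.flowfield import ConstantFlow, FlowFieldConfig, build_lookup_table, solve_network_flow
from swarmsteer.magnetics import MagneticParams, limit_gradient
from swarmsteer.steering import ConstantPolicy


class TestSemiStaticVelocity:
    def test_force_free_is_pure_advection(self):
        vf = np.array([0.01, -0.002])
        assert np.allclose(semi_static_velocity(np.zeros(2), vf, 1e-3, 75e-9), vf)

    def test_stock_drift_speed_at_max_gradient(self):
        # F = 1.288e-12 N balanced by Stokes drag on a 75 nm particle
        from swarmsteer.magnetics import magnetic_force

        F = magnetic_force(MagneticParams(), limit_gradient((1.0, 0.0), 1000.0))
        v = semi_static_velocity(F, np.zeros(2), 1e-3, 75e-9)
        assert np.linalg.norm(v) == pytest.approx(1.82e-3, rel=5e-3)

    def test_doubling_viscosity_halves_drift(self):
        F = np.array([1e-12, 0.0])
        v1 = semi_static_velocity(F, np.zeros(2), 1e-3, 75e-9)
        v2 = semi_static_velocity(F, np.zeros(2), 2e-3, 75e-9)
        assert np.allclose(v1, 2 * v2)


class TestSimConfig:
    def test_two_rate_contract(self):
        cfg = SimConfig()
        assert cfg.dt_minor == 0.05 / 25 == 0.002
        assert cfg.dt_minor * cfg.minors_per_major == pytest.approx(cfg.major_period, abs=1e-15)

    def test_inconsistent_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(dt_minor=0.003)


class TestSeeding:
    def test_clump_places_all_particles_in_square(self, comb_polygon):
        spec = SeedSpec()
        state = seed_particles(spec, 500, rng_seed=1, lumen=comb_polygon)
        assert state.n == 500
        assert (state.status == ACTIVE).all()
        c = np.asarray(spec.clump_center)
        assert (np.abs(state.positions - c) <= spec.clump_side / 2).all()

    def test_split_divides_equally(self, comb_polygon):
        spec = SeedSpec(mode="split")
        state = seed_particles(spec, 500, rng_seed=1, lumen=comb_polygon)
        c1, c2 = np.asarray(spec.clump_center), np.asarray(spec.second_center)
        in_first = (np.abs(state.positions - c1) <= spec.clump_side / 2).all(axis=1)
        in_second = (np.abs(state.positions - c2) <= spec.second_side / 2).all(axis=1)
        assert in_first.sum() == 250 and in_second.sum() == 250

    def test_split_odd_count_rounds_up_first(self, comb_polygon):
        state = seed_particles(SeedSpec(mode="split"), 5, rng_seed=0, lumen=comb_polygon)
        c1 = np.asarray(SeedSpec().clump_center)
        in_first = (np.abs(state.positions - c1) <= SeedSpec().clump_side / 2).all(axis=1)
        assert in_first.sum() == 3

    def test_same_seed_reproduces_positions(self, comb_polygon):
        a = seed_particles(SeedSpec(), 100, rng_seed=7, lumen=comb_polygon)
        b = seed_particles(SeedSpec(), 100, rng_seed=7, lumen=comb_polygon)
        assert np.array_equal(a.positions, b.positions)

    def test_square_outside_lumen_rejected(self, comb_polygon):
        bad = SeedSpec(clump_center=(1e-3, 1e-3))
        with pytest.raises(InvalidSeedError):
            seed_particles(bad, 10, rng_seed=0, lumen=comb_polygon)


class TestCollisions:
    def test_specular_reflection_off_horizontal_wall(self, straight_polygon):
        # wall at y = 0.5 mm; incoming velocity up-and-right bounces down
        p_prev = np.array([2.5e-3, 0.45e-3])
        v = np.array([1e-3, 1e-3])
        p_prop = p_prev + v * 0.1  # well past the wall
        p, v_out, stuck = resolve_collision(p_prev, p_prop, v, straight_polygon, mu=0.0)
        assert not stuck
        assert v_out == pytest.approx([1e-3, -1e-3], rel=1e-9)
        assert straight_polygon.contains(p)

    def test_elastic_collision_preserves_speed(self, straight_polygon):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p_prev = np.array([rng.uniform(1e-3, 4e-3), rng.uniform(-4.9e-4, 4.9e-4)])
            v = rng.normal(size=2) * 5e-3
            p_prop = p_prev + v * 0.002
            if straight_polygon.contains(p_prop):
                continue
            _, v_out, stuck = resolve_collision(p_prev, p_prop, v, straight_polygon, mu=0.0)
            if not stuck:
                assert np.linalg.norm(v_out) == pytest.approx(np.linalg.norm(v), rel=1e-12)

    def test_full_friction_kills_tangential_component(self, straight_polygon):
        p_prev = np.array([2.5e-3, 0.45e-3])
        v = np.array([1e-3, 1e-3])
        p_prop = p_prev + v * 0.1
        _, v_out, _ = resolve_collision(p_prev, p_prop, v, straight_polygon, mu=1.0)
        assert v_out[0] == pytest.approx(0.0, abs=1e-18)
        assert v_out[1] == pytest.approx(-1e-3, rel=1e-9)

    def test_corrected_position_is_inside(self, straight_polygon):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p_prev = np.array([rng.uniform(1e-4, 4.9e-3), rng.uniform(-4.99e-4, 4.99e-4)])
            v = rng.normal(size=2) * 0.02
            p_prop = p_prev + v * 0.002
            if straight_polygon.contains(p_prop):
                continue
            p, _, _ = resolve_collision(p_prev, p_prop, v, straight_polygon, mu=0.0)
            assert straight_polygon.contains_batch(p[None, :], tol=1e-9)[0]


class TestStepping:
    def test_zero_gradient_uniform_flow_translates(self, straight_graph, straight_polygon):
        cfg = SimConfig(n_particles=10, gradient_limit_mT_m=500.0)
        state = seed_particles(
            SeedSpec(clump_center=(1e-3, 0.0), clump_side=0.4e-3), 10, 3, straight_polygon
        )
        before = state.positions.copy()
        flow = ConstantFlow((0.01, 0.0))
        cmd = limit_gradient((0.0, 0.0), 500.0)
        minor_step(state, cmd, flow, straight_polygon, straight_graph, cfg, MagneticParams())
        assert np.allclose(state.positions - before, [0.01 * cfg.dt_minor, 0.0])
        assert state.t == pytest.approx(cfg.dt_minor)

    def test_particle_next_to_gate_exits_with_goal_id(self, straight_graph, straight_polygon):
        cfg = SimConfig(n_particles=1, gradient_limit_mT_m=500.0)
        state = seed_particles(
            SeedSpec(clump_center=(4.9e-3, 0.0), clump_side=1e-5), 1, 0, straight_polygon
        )
        flow = ConstantFlow((0.06, 0.0))  # 0.12 mm per minor step
        cmd = limit_gradient((0.0, 0.0), 500.0)
        minor_step(state, cmd, flow, straight_polygon, straight_graph, cfg, MagneticParams())
        assert state.status[0] == EXITED
        assert state.exit_outlet[0] == "out"

    def test_major_step_advances_clock_exactly_one_period(self, straight_graph, straight_polygon):
        cfg = SimConfig(n_particles=5)
        state = seed_particles(
            SeedSpec(clump_center=(1e-3, 0.0), clump_side=0.4e-3), 5, 0, straight_polygon
        )
        policy = ConstantPolicy((0.0, 0.0))
        flow = ConstantFlow((0.001, 0.0))
        state, rec = major_step(state, policy, flow, straight_polygon, straight_graph, cfg, MagneticParams())
        assert state.t == 0.05
        state, rec = major_step(state, policy, flow, straight_polygon, straight_graph, cfg, MagneticParams())
        assert state.t == 0.10
        assert rec.t == 0.10

    def test_advection_never_crosses_side_walls(self, straight_graph, straight_polygon):
        """Parabolic flow is wall-parallel: advected particles stay in the lumen."""
        sol = solve_network_flow(straight_graph, FlowFieldConfig(inlet_central_velocity=0.06))
        table = build_lookup_table(straight_graph, sol, lumen=straight_polygon)
        cfg = SimConfig(n_particles=200)
        state = seed_particles(
            SeedSpec(clump_center=(0.5e-3, 0.0), clump_side=0.9e-3), 200, 9, straight_polygon
        )
        cmd = limit_gradient((0.0, 0.0), 500.0)
        for _ in range(50):
            minor_step(state, cmd, table, straight_polygon, straight_graph, cfg, MagneticParams())
            act = state.status == ACTIVE
            assert straight_polygon.contains_batch(state.positions[act], tol=1e-9).all()
            # never exited sideways: every exit is through the end gate
            for i in np.flatnonzero(state.status == EXITED):
                assert state.exit_outlet[i] == "out"


class TestRunSimulation:
    def _run(self, graph, polygon, flow, cfg, spec, policy=None):
        return run_simulation(
            cfg, graph, flow, policy or ConstantPolicy((0.0, 0.0)), spec,
            params=MagneticParams(), polygon=polygon,
        )

    def test_swarm_next_to_gate_exits_in_one_major_step(self, straight_graph, straight_polygon):
        cfg = SimConfig(n_particles=20, max_sim_time=5.0)
        spec = SeedSpec(clump_center=(4.9e-3, 0.0), clump_side=1e-5)
        log = self._run(straight_graph, straight_polygon, ConstantFlow((0.06, 0.0)), cfg, spec)
        assert len(log.records) == 1
        assert (log.outcomes["exit_outlet"] == "out").all()

    def test_zero_time_budget_gives_empty_log(self, straight_graph, straight_polygon):
        cfg = SimConfig(n_particles=5, max_sim_time=0.0)
        spec = SeedSpec(clump_center=(1e-3, 0.0), clump_side=0.4e-3)
        log = self._run(straight_graph, straight_polygon, ConstantFlow((0.01, 0.0)), cfg, spec)
        assert log.records == []
        assert (log.outcomes["status"] == "active").all()

    def test_fixed_seed_rerun_is_bit_identical(self, straight_graph, straight_polygon):
        cfg = SimConfig(n_particles=50, rng_seed=13, max_sim_time=1.0)
        spec = SeedSpec(clump_center=(1e-3, 0.0), clump_side=0.4e-3)
        flow = ConstantFlow((0.004, 0.0))
        a = self._run(straight_graph, straight_polygon, flow, cfg, spec)
        b = self._run(straight_graph, straight_polygon, flow, cfg, spec)
        assert len(a.records) == len(b.records)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.positions, rb.positions)

    def test_particle_count_conserved_through_run(self, comb_graph, comb_polygon, comb_flow):
        cfg = SimConfig(n_particles=100, max_sim_time=3.0, gradient_limit_mT_m=500.0)
        log = run_simulation(
            cfg, comb_graph, comb_flow, ConstantPolicy((0.0, -0.2)), SeedSpec(),
            params=MagneticParams(), polygon=comb_polygon,
        )
        counts = log.outcomes["status"].value_counts()
        assert counts.sum() == 100

    def test_timestep_refinement_consistency(self, straight_graph, straight_polygon):
        """Halving dt (doubling the minor count) shifts trajectories by O(dt)."""
        sol = solve_network_flow(straight_graph, FlowFieldConfig(inlet_central_velocity=0.01))
        table = build_lookup_table(straight_graph, sol, spacing=2e-5, lumen=straight_polygon)
        spec = SeedSpec(clump_center=(0.5e-3, 0.0), clump_side=0.4e-3)
        ends = {}
        for dt, minors in ((0.002, 25), (0.001, 50)):
            cfg = SimConfig(
                dt_minor=dt, minors_per_major=minors, n_particles=20,
                max_sim_time=0.2, gradient_limit_mT_m=500.0,
            )
            log = run_simulation(
                cfg, straight_graph, table, ConstantPolicy((0.1, 0.3)), spec,
                params=MagneticParams(), polygon=straight_polygon,
            )
            ends[dt] = log.records[-1].positions
        drift = np.linalg.norm(ends[0.002] - ends[0.001], axis=1).max()
        # first-order integrator on a smooth shear field: error ~ v * dt
        assert drift < 5e-5
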