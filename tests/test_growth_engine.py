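import math

import numpy as np
import pytest

from tadcord import (
    GradientField, InteractionParams, NoiseSpec, SpatialHash, StepParams,
    build_schedule, build_standard_environment, grow_all, growth_step,
    make_toy_scenario, make_type_population, nearest_axon_point, null_field,
)
from tadcord.fixtures import _neuron, _quiet_noise
from tadcord.growth_engine import GrowthState, UsageError, _make_state, commissural_update
from tadcord.population import _wrap


def _state(neuron, seed=1):
    return _make_state(neuron, "primary", 0.0, 1.0, seed)


class TestNearestAxonPoint:
    def test_unique_in_range_point(self):
        cands = [(0.5, 0.0, 0.3, 1, 0), (2.0, 0.0, 1.0, 2, 0)]
        pt, theta = nearest_axon_point((0.0, 0.0), cands, 1.0)
        assert pt == (0.5, 0.0) and theta == 0.3

    def test_absent_when_nothing_in_range(self):
        assert nearest_axon_point((0.0, 0.0), [(5.0, 0.0, 1.0, 1, 0)], 1.0) is None

    def test_self_points_excluded(self):
        cands = [(0.1, 0.0, 0.5, 7, 0), (0.9, 0.0, 0.8, 3, 2)]
        pt, theta = nearest_axon_point((0.0, 0.0), cands, 1.0, exclude_neuron=7)
        assert theta == 0.8

    def test_tie_broken_by_neuron_then_step(self):
        cands = [(1.0, 0.0, 0.1, 5, 9), (-1.0, 0.0, 0.2, 2, 3), (0.0, 1.0, 0.3, 2, 1)]
        pt, theta = nearest_axon_point((0.0, 0.0), cands, 1.5)
        assert theta == 0.3  # all at distance 1: lowest (neuron, step) wins

    def test_spatial_hash_matches_brute_force(self):
        """1000 random instances: hash result identical to exhaustive scan."""
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            pts = list(
                zip(
                    rng.uniform(0, 20, n), rng.uniform(0, 20, n),
                    rng.uniform(-3, 3, n), rng.integers(0, 6, n).tolist(),
                    rng.integers(0, 100, n).tolist(),
                )
            )
            pts = [(float(a), float(b), float(c), int(d), int(e))
                   for a, b, c, d, e in pts]
            h = SpatialHash(1.0)
            for p in pts:
                h.insert(*p)
            tip = (float(rng.uniform(0, 20)), float(rng.uniform(0, 20)))
            ex = int(rng.integers(0, 6))
            assert h.query_nearest(tip[0], tip[1], 1.0, ex) == nearest_axon_point(
                tip, pts, 1.0, ex
            )


class TestGrowthStep:
    def test_angle_update_formula(self, std_env):
        """theta = 0, g_rc = 0.1, g_dv = 0.05, no noise, s = 0 -> 0.05."""
        n = _neuron(0, "dIN", 1, (1000.0, 50.0), 0.0, 10.0)
        st = _state(n)
        field = GradientField()
        field = field.with_type_params("dIN", k_rc=0.1, k_dv=0.05, k_off=0.0)
        # at y = 50, g_dv = 0.05*exp(-50/40); use lam large to make it 0.05
        from dataclasses import replace
        field = replace(field, lam=1e12)
        growth_step(st, field, _quiet_noise(), InteractionParams(0, 0, 1),
                    None, std_env)
        assert st.thetas[0] == pytest.approx(0.05)

    def test_full_attraction_overrides_gradients(self, std_env):
        n = _neuron(0, "dIN", 1, (1000.0, 50.0), 0.0, 10.0)
        st = _state(n)
        growth_step(
            st, GradientField(), NoiseSpec(), InteractionParams(1.0, 1.0, 1.0),
            ((1000.2, 50.2), 0.7), std_env,
        )
        assert st.thetas[0] == pytest.approx(0.7)

    def test_blend_midpoint(self, std_env):
        n = _neuron(0, "dIN", 1, (1000.0, 50.0), 0.2, 10.0)
        st = _state(n)
        growth_step(
            st, null_field(), _quiet_noise(), InteractionParams(0.5, 0.5, 1.0),
            ((1000.1, 50.1), 0.6), std_env,
        )
        # theta_A = 0.2 (no gradients/noise), theta_B = 0.6, s = 0.5 -> 0.4
        assert st.thetas[0] == pytest.approx(0.4)

    def test_inactive_state_rejected(self, std_env):
        n = _neuron(0, "dIN", 1, (1000.0, 50.0), 0.0, 10.0)
        st = _state(n)
        st.active = False
        with pytest.raises(UsageError):
            growth_step(st, GradientField(), NoiseSpec(),
                        InteractionParams(0, 0, 1), None, std_env)

    def test_step_length_conservation(self, std_env, default_field):
        pop = make_type_population("aIN", 6, 2, seed=9, length=150.0)
        trajs = grow_all(pop, std_env, default_field,
                         InteractionParams(0.3, 0.3, 1.0), seed=9)
        for t in trajs.values():
            seg = np.diff(t.points, axis=0)
            d = np.hypot(seg[:, 0], seg[:, 1])
            unclipped = ~t.clipped
            assert np.allclose(d[unclipped], 1.0)


class TestCommissuralUpdate:
    def test_crossing_transitions_at_contralateral_floor_boundary(self, std_env):
        n = _neuron(0, "cIN", 1, (1200.0, 30.0), -math.pi / 2, 120.0)
        st = _state(n)
        assert st.phase == "pre_crossing"
        ys = [30.0 - k for k in range(1, 57)]  # straight ventral descent
        for y in ys:
            st.xs.append(1200.0)
            st.ys.append(y)
            st.thetas.append(-math.pi / 2)
            commissural_update(st, std_env)
            st.point_phases.append(st.phase)
        first_crossed = next(i for i, p in enumerate(st.point_phases) if p == "crossed")
        assert st.ys[first_crossed] == -25.0  # first point at |y| >= 25 contralateral

    def test_meandering_without_midline_crossing_stays_pre_crossing(self, std_env):
        n = _neuron(0, "cIN", 1, (1200.0, 30.0), -math.pi / 2, 60.0)
        st = _state(n)
        for y in [20.0, 10.0, 5.0, 10.0, 20.0, 24.0]:
            st.xs.append(1200.0)
            st.ys.append(y)
            st.thetas.append(0.0)
            commissural_update(st, std_env)
            st.point_phases.append(st.phase)
        assert st.phase == "pre_crossing"

    def test_non_commissural_rejected(self, std_env):
        n = _neuron(0, "dIN", 1, (1000.0, 50.0), 0.0, 10.0)
        with pytest.raises(UsageError):
            commissural_update(_state(n), std_env)

    def test_pre_crossing_suppresses_interaction(self, std_env):
        n = _neuron(0, "cIN", 1, (1200.0, 55.0), -1.6, 60.0)
        st = _state(n)
        before = st.tip_angle
        growth_step(
            st, null_field(), _quiet_noise(), InteractionParams(1.0, 1.0, 1.0),
            ((1200.1, 55.1), 0.9), std_env,
        )
        # neighbour ignored entirely: angle stays theta_A = theta_0
        assert st.thetas[0] == pytest.approx(_wrap(before))

    def test_end_to_end_crossing(self, std_env):
        sc = make_toy_scenario("commissural_single")
        trajs = grow_all(sc.population, sc.environment, sc.fields,
                         sc.interaction, seed=2, noise=sc.noise)
        t = trajs[(0, "primary")]
        crossed = t.point_phases == "crossed"
        assert crossed.any()
        i = int(np.argmax(crossed))
        assert t.points[i, 1] <= -25.0
        # all crossed-phase points contralateral to the (left) soma
        assert (t.points[crossed][:, 1] < 0).all()


class TestSchedule:
    def test_pioneers_then_followers_rostral_first(self, tables):
        from tadcord.population import PopulationConfig, build_population
        pop = build_population(
            PopulationConfig(counts={"dla": 12}, pioneers={"dla": 2}), tables, 4
        )
        left = [n for n in pop if n.side > 0]
        start = build_schedule(left, wave_spacing=200.0)
        pio_steps = max(
            math.ceil(n.primary_length) for n in left if n.pioneer_primary
        )
        followers = sorted(
            (n for n in left if not n.pioneer_primary), key=lambda n: n.soma[0]
        )
        for k, n in enumerate(followers):
            assert start[(n.id, "primary")] == pio_steps + k * 200.0
        for n in left:
            if n.pioneer_primary:
                assert start[(n.id, "primary")] == 0.0

    def test_explicit_follower_times(self):
        """4 pioneers of length 500 + 2 followers -> starts at 500 and 700."""
        neurons = [
            _neuron(i, "dla", 1, (1900.0 - 100.0 * i, 50.0), math.pi, 500.0,
                    pioneer=True)
            for i in range(4)
        ]
        neurons += [
            _neuron(4, "dla", 1, (1100.0, 50.0), math.pi, 300.0),
            _neuron(5, "dla", 1, (1300.0, 50.0), math.pi, 300.0),
        ]
        start = build_schedule(neurons, wave_spacing=200.0)
        assert start[(4, "primary")] == 500.0  # more rostral follower first
        assert start[(5, "primary")] == 700.0

    def test_secondary_wave_after_all_primaries(self, tables):
        from tadcord.population import PopulationConfig, build_population
        pop = build_population(
            PopulationConfig(counts={"RB": 10}, pioneers={"RB": 2}), tables, 4
        )
        start = build_schedule(pop, wave_spacing=200.0)
        last_primary_finish = max(
            start[(n.id, "primary")] + math.ceil(n.primary_length) for n in pop
        )
        sec_starts = [v for (nid, klass), v in start.items() if klass == "secondary"]
        assert sec_starts and min(sec_starts) >= last_primary_finish


class TestGrowAll:
    def test_s0_matches_solo_growth_bit_exactly(self, std_env, default_field,
                                                no_interaction):
        pop = make_type_population("aIN", 8, 2, seed=6, primary_only=False)
        joint = grow_all(pop, std_env, default_field, no_interaction, seed=5)
        for n in pop:
            solo = grow_all([n], std_env, default_field, no_interaction, seed=5)
            for key, t in solo.items():
                assert np.array_equal(t.points, joint[key].points)
                assert np.array_equal(t.angles, joint[key].angles)

    def test_same_seed_bit_identical(self, std_env, default_field):
        pop = make_type_population("dla", 10, 2, seed=8)
        ia = InteractionParams(0.3, 0.3, 1.0)
        t1 = grow_all(pop, std_env, default_field, ia, seed=3)
        t2 = grow_all(pop, std_env, default_field, ia, seed=3)
        for k in t1:
            assert np.array_equal(t1[k].points, t2[k].points)

    def test_interaction_locality_other_types_irrelevant(self, std_env,
                                                         default_field):
        """Deleting all other-type axons never changes a type's trajectories."""
        pop_a = make_type_population("dla", 8, 2, seed=7, length=200.0)
        pop_b = make_type_population("mn", 6, 2, seed=17, length=200.0)
        for i, n in enumerate(pop_b):
            n.id = 1000 + i
        ia = InteractionParams(0.4, 0.4, 1.0)
        mixed = grow_all(pop_a + pop_b, std_env, default_field, ia, seed=11)
        alone = grow_all(pop_a, std_env, default_field, ia, seed=11)
        for k in alone:
            assert np.array_equal(alone[k].points, mixed[k].points)

    def test_follower_locks_to_pioneer_at_s1(self):
        sc = make_toy_scenario("straight_pioneer_follower")
        trajs = grow_all(sc.population, sc.environment, sc.fields,
                         sc.interaction, seed=1, noise=sc.noise)
        follower = trajs[(1, "primary")]
        assert np.allclose(follower.angles, math.pi)

    def test_repelled_follower_takes_away_perpendicular(self):
        sc = make_toy_scenario("straight_pioneer_follower")
        ia = InteractionParams(-1.0, -1.0, 1.0)
        trajs = grow_all(sc.population, sc.environment, sc.fields, ia,
                         seed=1, noise=sc.noise)
        follower = trajs[(1, "primary")]
        # the follower starts below the pioneer: away-perpendicular is -pi/2
        assert follower.angles[0] == pytest.approx(-math.pi / 2)

    def test_points_stay_inside_arena(self, std_env, default_field):
        pop = make_type_population("mn", 8, 2, seed=13, x_range=(600.0, 1500.0))
        trajs = grow_all(pop, std_env, default_field,
                         InteractionParams(0.2, 0.2, 1.0), seed=13)
        arena = std_env.arena
        for t in trajs.values():
            assert (t.points[:, 0] >= arena.x_min - 1e-9).all()
            assert (t.points[:, 0] <= arena.x_max + 1e-9).all()
            assert (np.abs(t.points[:, 1]) <= arena.y_abs_max + 1e-9).all()

    def test_secondary_sprouts_at_branch_point_opposite_direction(
            self, std_env, default_field, no_interaction):
        pop = make_type_population("RB", 4, 1, seed=21, primary_only=False)
        trajs = grow_all(pop, std_env, default_field, no_interaction, seed=21)
        for n in pop:
            if n.secondary_length is None:
                continue
            prim = trajs[(n.id, "primary")]
            sec = trajs[(n.id, "secondary")]
            k = min(int(round(n.branch_arc_length)), len(prim.points) - 1)
            assert np.allclose(sec.points[0], prim.points[k])
            # primary ascends (-x), secondary descends (+x)
            assert sec.points[-1, 0] > sec.points[0, 0] - 50.0
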