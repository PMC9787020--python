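"""Simulator: forces, integration, statuses, spawning, trial semantics."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy.stats import kstest

from herdlab import (
    PolicyConfig,
    WorldConfig,
    repulsion_force,
    run_trial,
    sample_brownian_force,
    step_world,
    update_statuses,
)
from herdlab.simulate import (
    ALL_CONTAINED,
    CONTAINED,
    FLEEING,
    IDLE,
    WorldState,
    _corral_goal,
    make_policy_state,
    policy_act,
    policy_observe,
    spawn_positions,
)

CENTER = (250.0, 250.0)


def make_state(ta_pos, avatar_pos, config, ta_vel=None):
    k = len(ta_pos)
    state = WorldState(
        t=0.0,
        ta_pos=np.asarray(ta_pos, dtype=float),
        ta_vel=np.asarray(ta_vel, dtype=float) if ta_vel is not None else np.zeros((k, 2)),
        ta_brownian=np.zeros((k, 2)),
        ta_status=np.zeros(k, dtype=np.int8),
        avatar_pos=np.asarray(avatar_pos, dtype=float),
        avatar_heading=np.zeros(3),
        avatar_slow=np.zeros(3, dtype=bool),
    )
    return update_statuses(state, config)


IDLE_CONTROLS = [
    {"move_dir": np.zeros(2), "slow": False, "head": 0.0} for _ in range(3)
]

FAR_AVATARS = np.array([[10.0, 10.0], [20.0, 10.0], [10.0, 20.0]])


class TestWorldConfig:
    def test_defaults_are_valid(self):
        WorldConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"avatar_speed_slow": 10.0},  # must be < avatar_speed
            {"success_hold": 400.0},  # must be < trial_max
            {"ta_spawn_radius": 5.0},  # must exceed containment diameter
            {"n_targets": 0},
            {"arena_side": -1.0},
            {"physics_hz": 90, "log_hz": 7},  # must divide
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WorldConfig(**kwargs)


class TestBrownianForce:
    def test_magnitude_bounds_over_many_draws(self, rng):
        f = sample_brownian_force(rng, 60.0, size=10_000)
        mags = np.hypot(f[:, 0], f[:, 1])
        assert mags.min() >= 0.0
        assert mags.max() <= 60.0

    def test_mean_magnitude_is_half_the_cap(self, rng):
        f = sample_brownian_force(rng, 60.0, size=100_000)
        mags = np.hypot(f[:, 0], f[:, 1])
        assert np.mean(mags) == pytest.approx(30.0, abs=0.5)

    def test_zero_cap_gives_zero_vector(self, rng):
        f = sample_brownian_force(rng, 0.0, size=100)
        np.testing.assert_array_equal(f, 0.0)


class TestRepulsionForce:
    def test_zero_outside_interaction_radius(self):
        f = repulsion_force([11.0, 0.0], [0.0, 0.0], WorldConfig())
        np.testing.assert_array_equal(f, 0.0)

    def test_capped_at_contact(self):
        f = repulsion_force([1e-6, 0.0], [0.0, 0.0], WorldConfig())
        assert np.hypot(*f) == pytest.approx(450.0)

    def test_inverse_distance_law_at_five_meters(self):
        f = repulsion_force([5.0, 0.0], [0.0, 0.0], WorldConfig())
        assert np.hypot(*f) == pytest.approx(90.0)
        # directed from avatar toward TA
        assert f[0] > 0 and f[1] == 0

    def test_coincident_positions_fall_back_deterministically(self):
        f = repulsion_force([2.0, 3.0], [2.0, 3.0], WorldConfig())
        np.testing.assert_array_equal(f, [450.0, 0.0])


class TestStepWorld:
    def test_unforced_velocity_decays_monotonically(self):
        config = WorldConfig()
        state = make_state([[100.0, 100.0]], FAR_AVATARS, config,
                           ta_vel=[[6.0, 0.0]])
        speeds = []
        for _ in range(200):
            step_world(state, IDLE_CONTROLS, config)
            speeds.append(float(np.hypot(*state.ta_vel[0])))
        assert all(a >= b for a, b in zip(speeds, speeds[1:]))

    def test_speed_cap_never_exceeded(self):
        config = dataclasses.replace(WorldConfig(), brownian_force_max=500.0)
        rng = np.random.default_rng(0)
        state = make_state([[250.0, 250.0]] * 5, FAR_AVATARS, config)
        for step in range(10_000):
            if step % 90 == 0:
                state.ta_brownian = sample_brownian_force(rng, 500.0, 5)
            step_world(state, IDLE_CONTROLS, config)
            speeds = np.hypot(state.ta_vel[:, 0], state.ta_vel[:, 1])
            assert np.all(speeds <= config.ta_speed_max + 1e-9)

    def test_hand_computed_euler_step(self):
        """One step: acceleration is the unit vector from avatar to TA."""
        config = WorldConfig()
        avatars = np.array([[245.0, 250.0], [20.0, 10.0], [10.0, 20.0]])
        state = make_state([[250.0, 250.0]], avatars, config)
        step_world(state, IDLE_CONTROLS, config)
        # repulsion min(450, 450/5) = 90 N along +x; drag is zero at v=0
        dt = 1.0 / 90.0
        np.testing.assert_allclose(state.ta_vel[0], [90.0 * dt, 0.0], atol=1e-12)

    def test_nan_state_raises(self):
        config = WorldConfig()
        state = make_state([[250.0, 250.0]], FAR_AVATARS, config)
        state.ta_vel[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            step_world(state, IDLE_CONTROLS, config)


class TestStatuses:
    def test_all_inside_disc_is_all_contained(self):
        config = WorldConfig()
        state = make_state([[250.0, 250.0], [252.0, 251.0]], FAR_AVATARS, config)
        assert np.all(state.ta_status == ALL_CONTAINED)

    def test_boundary_is_closed(self):
        config = WorldConfig()
        state = make_state([[255.0, 250.0], [100.0, 100.0]], FAR_AVATARS, config)
        assert state.ta_status[0] == CONTAINED

    def test_fleeing_outside_disc_with_avatar_near(self):
        config = WorldConfig()
        avatars = np.array([[109.9, 100.0], [20.0, 10.0], [10.0, 20.0]])
        state = make_state([[100.0, 100.0]], avatars, config)
        assert state.ta_status[0] == FLEEING

    def test_containment_overrides_fleeing(self):
        config = WorldConfig()
        avatars = np.array([[253.0, 250.0], [20.0, 10.0], [10.0, 20.0]])
        state = make_state([[250.0, 250.0], [100.0, 100.0]], avatars, config)
        assert state.ta_status[0] == CONTAINED
        assert state.ta_status[1] == IDLE


class TestSpawning:
    def test_spawn_radii_and_disc_uniformity(self):
        rng = np.random.default_rng(42)
        center = np.array(CENTER)
        r_all = []
        for _ in range(1000):
            tas = spawn_positions(rng, center, 180.0, 9)
            avs = spawn_positions(rng, center, 100.0, 3)
            assert np.all(np.hypot(*(tas - center).T) <= 180.0)
            assert np.all(np.hypot(*(avs - center).T) <= 100.0)
            r_all.extend(np.hypot(*(tas - center).T))
        # area-uniform on a disc: (r/R)^2 ~ U(0,1)
        u = (np.asarray(r_all) / 180.0) ** 2
        assert kstest(u, "uniform").pvalue > 0.01

    def test_trial_initial_positions_respect_spawn_radii(self):
        config = dataclasses.replace(WorldConfig(), trial_max=2.0, success_hold=1.0)
        policy = PolicyConfig()
        for seed in range(5):
            log, _ = run_trial(config, [policy] * 3, seed)
            center = np.array(CENTER)
            assert np.all(np.hypot(*(log.ta_pos[0] - center).T) <= 180.0)
            assert np.all(np.hypot(*(log.player_pos[0] - center).T) <= 100.0)


class TestTrialSemantics:
    def test_constructed_hold_ends_after_exactly_five_seconds(self):
        """All TAs start contained and undisturbed: success at hold time."""
        config = dataclasses.replace(WorldConfig(), brownian_force_max=0.0, n_targets=3)
        policy = PolicyConfig(strategy="corral_nearest", global_info=True)
        inside = np.array([[250.0, 250.0], [251.0, 250.0], [250.0, 251.0]])
        log, outcome = run_trial(
            config, [policy] * 3, seed=0,
            initial_ta_positions=inside,
            initial_avatar_positions=np.array([[300.0, 250.0], [200.0, 250.0],
                                               [250.0, 300.0]]),
        )
        assert outcome == "success"
        assert log.duration == pytest.approx(config.success_hold, abs=1.5 / 90.0)

    def test_hold_timer_resets_on_exit(self):
        """An avatar parked on a contained TA ejects it, so the first
        all-contained streak breaks and success comes much later."""
        config = dataclasses.replace(WorldConfig(), brownian_force_max=0.0, n_targets=1)
        policy = PolicyConfig(strategy="corral_nearest", global_info=True,
                              heading_noise_sd=0.0)
        log, outcome = run_trial(
            config, [policy] * 3, seed=0,
            initial_ta_positions=np.array([[252.0, 250.0]]),
            initial_avatar_positions=np.array([[249.0, 250.0], [200.0, 250.0],
                                               [250.0, 200.0]]),
        )
        # the trial must not have ended 5 s after the initial contained state
        assert log.duration > config.success_hold + 1.0
        if outcome == "success":
            # completed hold must span the final 5 s exactly
            all_contained = np.all(log.ta_status == ALL_CONTAINED, axis=1)
            start = len(all_contained) - 1
            while start > 0 and all_contained[start - 1]:
                start -= 1
            held = log.duration - log.time[start]
            assert held == pytest.approx(config.success_hold, abs=2.0 / 90.0)

    def test_immobile_world_fails_at_ceiling(self):
        """Nothing moves, nothing becomes contained: censored at 300 s."""
        config = dataclasses.replace(WorldConfig(), brownian_force_max=0.0, n_targets=2)
        # blind players never see a TA and sweep forever
        policy = PolicyConfig(strategy="partitioned_sweep", global_info=False,
                              sense_radius=1e-6)
        log, outcome = run_trial(
            config, [policy] * 3, seed=1,
            initial_ta_positions=np.array([[400.0, 400.0], [420.0, 420.0]]),
        )
        assert outcome == "fail"
        assert log.duration == config.trial_max

    def test_same_seed_gives_bit_identical_logs(self):
        config = dataclasses.replace(WorldConfig(), trial_max=10.0, n_targets=3)
        policy = PolicyConfig()
        log1, _ = run_trial(config, [policy] * 3, seed=5)
        log2, _ = run_trial(config, [policy] * 3, seed=5)
        np.testing.assert_array_equal(log1.player_pos, log2.player_pos)
        np.testing.assert_array_equal(log1.ta_pos, log2.ta_pos)
        np.testing.assert_array_equal(log1.player_heading, log2.player_heading)
        np.testing.assert_array_equal(log1.ta_status, log2.ta_status)
        assert log1.duration == log2.duration

    def test_wrong_policy_count_rejected(self):
        with pytest.raises(ValueError):
            run_trial(WorldConfig(), [PolicyConfig()] * 2, seed=0)


class TestObservations:
    def test_global_observation_exposes_everything(self):
        config = WorldConfig()
        state = make_state([[250.0, 250.0]] * 9, FAR_AVATARS, config)
        obs = policy_observe(state, PolicyConfig(global_info=True), 0, config)
        assert obs["ta_mask"].sum() == 9
        assert obs["player_mask"].sum() == 3

    def test_fog_masks_distant_targets(self):
        config = WorldConfig()
        state = make_state([[100.0, 100.0]], FAR_AVATARS, config)
        obs = policy_observe(
            state, PolicyConfig(global_info=False, sense_radius=10.0), 0, config
        )
        assert obs["ta_mask"].sum() == 0

    def test_fog_sees_fewer_targets_than_clear(self, short_trial_log):
        """Mean visible TAs per sample: fog strictly below clear."""
        log = short_trial_log
        d = np.linalg.norm(
            log.ta_pos[:, None, :, :] - log.player_pos[:, :, None, :], axis=-1
        )  # (n, players, targets)
        fog = (d <= 10.0).sum(axis=2).mean()
        clear = (d <= 150.0).sum(axis=2).mean()
        assert fog < clear


class TestPolicies:
    def test_random_walk_directions_cover_the_circle(self):
        config = WorldConfig()
        pcfg = PolicyConfig(strategy="random_walk", global_info=False,
                            sense_radius=1.0, scan_amplitude=0.0,
                            heading_noise_sd=0.0)
        state = make_state([[400.0, 400.0]], FAR_AVATARS, config)
        ps = make_policy_state(pcfg, 0)
        rng = np.random.default_rng(0)
        vecs = []
        t = 0.0
        for _ in range(1000):
            obs = policy_observe(state, pcfg, 0, config)
            obs["t"] = t
            ctrl = policy_act(obs, ps, rng)
            vecs.append(ctrl["move_dir"])
            t += 30.0  # expire the waypoint so every call redraws
            ps["waypoint_deadline"] = -1.0
            ps["waypoint"] = None
        mean_resultant = np.linalg.norm(np.mean(vecs, axis=0))
        assert mean_resultant < 0.15

    def test_corral_goal_lies_beyond_target_on_outward_ray(self):
        config = WorldConfig()
        ta = np.array([280.0, 270.0])
        state = make_state([ta], FAR_AVATARS, config)
        obs = policy_observe(state, PolicyConfig(), 0, config)
        goal = _corral_goal(obs, 0, PolicyConfig())
        center = np.array(CENTER)
        out_ta = (ta - center) / np.linalg.norm(ta - center)
        out_goal = (goal - center) / np.linalg.norm(goal - center)
        np.testing.assert_allclose(out_goal, out_ta, atol=1e-12)
        assert np.linalg.norm(goal - center) > np.linalg.norm(ta - center)

    def test_degenerate_scan_head_equals_movement_heading(self):
        config = WorldConfig()
        pcfg = PolicyConfig(scan_amplitude=0.0, heading_noise_sd=0.0)
        state = make_state([[300.0, 250.0]], FAR_AVATARS, config)
        ps = make_policy_state(pcfg, 0)
        obs = policy_observe(state, pcfg, 0, config)
        ctrl = policy_act(obs, ps, np.random.default_rng(0))
        move = ctrl["move_dir"]
        assert ctrl["head"] == pytest.approx(np.arctan2(move[1], move[0]))

    def test_policy_config_validation(self):
        with pytest.raises(ValueError):
            PolicyConfig(strategy="teleport")
        with pytest.raises(ValueError):
            PolicyConfig(sense_radius=0.0)
        with pytest.raises(ValueError):
            PolicyConfig(scan_period=0.0)


class TestLoggedKinematics:
    def test_logged_speed_caps(self, failed_trial_log):
        """Per-frame displacements respect the TA and avatar speed caps."""
        log = failed_trial_log
        dt = 1.0 / log.sample_rate
        ta_step = np.linalg.norm(np.diff(log.ta_pos, axis=0), axis=-1)
        assert ta_step.max() <= 10.0 * dt + 1e-9
        av_step = np.linalg.norm(np.diff(log.player_pos, axis=0), axis=-1)
        assert av_step.max() <= 10.0 * dt + 1e-9

    def test_positions_stay_in_arena(self, failed_trial_log):
        log = failed_trial_log
        for track in (log.ta_pos, log.player_pos):
            assert track.min() >= 0.0
            assert track.max() <= 500.0
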