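"""Closed-loop simulator: arena dynamics, controller, cohort generation."""
import math

import numpy as np
import pytest

from sunflight import (
    FlyPhenotype,
    GroupSpec,
    SimConfig,
    broad_group_spec,
    closed_loop_step,
    flight_seed,
    fold_abs,
    frontal_group_spec,
    generate_cohort,
    simulate_flight,
    steering_policy,
    summarize_cohort,
    summarize_flight,
    wrap_deg,
    write_cohort,
)


class TestClosedLoopStep:
    def test_unit_wing_difference_accumulates_arena_gain(self):
        h = 0.0
        for _ in range(200):
            h = closed_loop_step(h, 1.0, 1 / 200)
        assert h == pytest.approx(4.75, abs=1e-9)

    def test_zero_wing_difference_leaves_heading(self):
        assert closed_loop_step(37.0, 0.0, 0.01) == 37.0

    def test_two_half_steps_equal_one_full_step(self):
        h1 = closed_loop_step(closed_loop_step(10.0, 2.0, 0.05), 2.0, 0.05)
        h2 = closed_loop_step(10.0, 2.0, 0.1)
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_positive_wing_diff_turns_rightward(self):
        assert closed_loop_step(0.0, 1.0, 1.0) > 0.0

    @pytest.mark.parametrize("dt", [0.0, -0.1])
    def test_nonpositive_dt_rejected(self, dt):
        with pytest.raises(ValueError, match="dt"):
            closed_loop_step(0.0, 1.0, dt)


class TestSteeringPolicy:
    def test_fixed_point_at_goal(self, rng):
        assert steering_policy(30.0, 30.0, k_p=1.0, sigma_w=0.0, rng=rng) == 0.0

    def test_sign_turns_stimulus_back_toward_goal(self, rng):
        w = steering_policy(90.0, 0.0, k_p=1.0, sigma_w=0.0, rng=rng)
        assert w < 0.0
        w = steering_policy(-90.0, 0.0, k_p=1.0, sigma_w=0.0, rng=rng)
        assert w > 0.0

    def test_error_wraps_across_seam(self, rng):
        # heading -170 vs goal 170: shortest error is +20, not -340
        w = steering_policy(-170.0, 170.0, k_p=1.0, sigma_w=0.0, rng=rng)
        assert w == pytest.approx(-(1.0 / 4.75) * 20.0)

    def test_noise_moment(self, rng):
        draws = np.array(
            [steering_policy(0.0, 0.0, 1.0, sigma_w=5.0, rng=rng) for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(0.0, abs=5 * 5.0 / math.sqrt(1e5))
        assert draws.std() == pytest.approx(5.0, rel=0.02)


def exponential_decay_oracle(start_err, k_p, duration_s, dt=1e-4):
    """Fine-step integration of de/dt = -k_p * e (independent of the simulator)."""
    e = start_err
    for _ in range(int(round(duration_s / dt))):
        e -= k_p * e * dt
    return e


class TestSimulateFlight:
    def test_noise_free_decay_matches_ode_oracle(self):
        cfg = SimConfig(duration_s=5.0)
        phen = FlyPhenotype(goal_deg=0.0, k_p=1.0, sigma_w=0.0)
        tr = simulate_flight(phen, cfg, seed=0, start_heading=-90.0)
        final = tr.heading[-1]
        assert abs(final) <= 1.0
        oracle = exponential_decay_oracle(-90.0, 1.0, tr.t[-1])
        # 60 Hz Euler vs fine-step integration of the continuous limit
        assert final == pytest.approx(oracle, abs=0.1)

    def test_constant_at_goal_with_zero_noise(self):
        cfg = SimConfig(duration_s=2.0)
        phen = FlyPhenotype(goal_deg=45.0, k_p=0.8, sigma_w=0.0)
        tr = simulate_flight(phen, cfg, seed=0, start_heading=45.0)
        assert np.allclose(tr.heading, 45.0)
        assert summarize_flight(tr).vector_strength == pytest.approx(1.0)

    def test_sample_count_and_determinism(self):
        cfg = SimConfig(duration_s=3.0)
        phen = FlyPhenotype(goal_deg=10.0, k_p=0.3, sigma_w=40.0)
        tr1 = simulate_flight(phen, cfg, seed=77, fly_id="x")
        tr2 = simulate_flight(phen, cfg, seed=77, fly_id="x")
        assert tr1.n_samples == int(3.0 * cfg.heading_rate_hz)
        np.testing.assert_array_equal(tr1.heading, tr2.heading)
        tr3 = simulate_flight(phen, cfg, seed=78)
        assert not np.array_equal(tr1.heading, tr3.heading)

    def test_zero_order_hold_piecewise_linear(self):
        """Between policy updates the heading advances linearly (held wing
        difference), mirroring 60 Hz control of a 200 Hz-sampled stimulus."""
        cfg = SimConfig(duration_s=1.0, heading_rate_hz=240.0, policy_rate_hz=60.0)
        phen = FlyPhenotype(goal_deg=0.0, k_p=0.5, sigma_w=15.0)
        tr = simulate_flight(phen, cfg, seed=5, start_heading=20.0)
        h = tr.heading  # 4 samples per policy interval; no wrap at these params
        for j in range(0, len(h) - 4, 4):
            seg = h[j : j + 5]
            diffs = np.diff(seg[:4])
            assert np.allclose(diffs, diffs[0], atol=1e-9)

    def test_vector_strength_decreases_with_wing_noise(self):
        cfg = SimConfig(duration_s=30.0)
        strengths = []
        for sigma in (10.0, 40.0, 80.0, 160.0):
            phen = FlyPhenotype(goal_deg=0.0, k_p=0.3, sigma_w=sigma)
            tr = simulate_flight(phen, cfg, seed=123, start_heading=0.0)
            strengths.append(summarize_flight(tr).vector_strength)
        assert strengths == sorted(strengths, reverse=True)

    def test_gain_conservation_noise_free(self):
        """Each policy interval's heading displacement equals gain x held
        wing difference x dt, so the total displacement is gain x the
        integral of the wing-stroke difference."""
        cfg = SimConfig(duration_s=4.0, heading_rate_hz=240.0, policy_rate_hz=60.0)
        phen = FlyPhenotype(goal_deg=0.0, k_p=0.6, sigma_w=0.0)
        tr = simulate_flight(phen, cfg, seed=0, start_heading=-60.0)
        dt_p = 1.0 / cfg.policy_rate_hz
        grid = tr.heading[::4]  # samples on the policy grid (240/60 = 4)
        integral = 0.0
        for j in range(len(grid) - 1):
            w_j = -(phen.k_p / cfg.gain) * grid[j]  # controller law, goal 0
            assert grid[j + 1] - grid[j] == pytest.approx(
                cfg.gain * w_j * dt_p, abs=1e-9
            )
            integral += w_j * dt_p
        assert grid[-1] - grid[0] == pytest.approx(cfg.gain * integral, abs=1e-6)

    def test_stops_recorded_consistently(self):
        cfg = SimConfig(duration_s=10.0, stop_rate_per_flight=3.0)
        phen = FlyPhenotype(goal_deg=0.0, k_p=0.3, sigma_w=20.0)
        hit = False
        for seed in range(5):
            tr = simulate_flight(phen, cfg, seed=seed)
            assert tr.n_stops == len(tr.stop_intervals)
            for a, b in tr.stop_intervals:
                assert 0.0 <= a <= b <= cfg.duration_s
            hit = hit or tr.n_stops > 0
        assert hit

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(duration_s=-1.0)
        with pytest.raises(ValueError):
            SimConfig(gain=0.0)
        with pytest.raises(ValueError):
            simulate_flight(FlyPhenotype(0.0, 0.3, 10.0), config=None, seed=0)


class TestGenerateCohort:
    CFG = SimConfig(duration_s=10.0, stop_rate_per_flight=0.0)

    def test_bookkeeping(self):
        # tight controller: flight means sit close to the per-fly goal even
        # over a short flight with a random start heading
        cohort = generate_cohort(
            [frontal_group_spec(n_flies=5, sigma_w=20.0, k_p=1.0)], self.CFG, seed=1
        )
        assert cohort.n_flies == 5
        traces = list(cohort.iter_flights())
        assert len(traces) == 10
        assert all(tr.n_samples == 2000 for tr in traces)
        assert all(tr.flight_type == "sun" for tr in traces)
        # both flights of a fly share the goal: their mean headings agree
        for fly in cohort.iter_flies():
            m = [summarize_flight(f).mean_heading for f in fly.flights]
            assert abs(wrap_deg(m[0] - m[1])) < 60.0

    def test_frontal_spec_folded_headings_are_frontal(self):
        cohort = generate_cohort(
            [frontal_group_spec(n_flies=8, kappa_frontal=8.0)], self.CFG, seed=2
        )
        folded = [s.abs_mean_heading for s in summarize_cohort(cohort)]
        assert np.mean(folded) < 90.0

    def test_same_seed_is_byte_identical_on_disk(self, tmp_path):
        specs = [frontal_group_spec(n_flies=2), broad_group_spec(n_flies=2)]
        m1 = write_cohort(generate_cohort(specs, self.CFG, seed=9), tmp_path / "a")
        m2 = write_cohort(generate_cohort(specs, self.CFG, seed=9), tmp_path / "b")
        assert m1.read_bytes() == m2.read_bytes()
        for p1 in sorted((tmp_path / "a" / "traces").iterdir()):
            assert p1.read_bytes() == (tmp_path / "b" / "traces" / p1.name).read_bytes()

    def test_flight_regenerable_in_isolation(self):
        spec = frontal_group_spec(n_flies=3, kappa_frontal=8.0)
        cohort = generate_cohort([spec], self.CFG, seed=4)
        fly = cohort.groups["frontal"][1]
        goal = None
        # re-derive the fly's phenotype and second sun flight from the seeds
        from sunflight.simulate import _draw_goal, _fly_rng

        fly_rng = _fly_rng(4, 0, 1)
        goal = _draw_goal(fly_rng, spec)
        regen = simulate_flight(
            FlyPhenotype(goal, spec.k_p, spec.sigma_w),
            self.CFG,
            flight_seed(4, 0, 1, 2),
            fly_id=fly.fly_id,
            group="frontal",
            flight_type="sun",
            flight_index=2,
        )
        orig = next(f for f in fly.flights if f.flight_index == 2)
        np.testing.assert_array_equal(regen.heading, orig.heading)

    def test_stripe_flights_generated_when_requested(self):
        cfg = SimConfig(duration_s=5.0, include_stripe=True, stop_rate_per_flight=0.0)
        cohort = generate_cohort([broad_group_spec(n_flies=3)], cfg, seed=5)
        stripes = [f for f in cohort.iter_flights() if f.flight_type == "stripe"]
        assert len(stripes) == 3
        # stripe goals are frontally biased (fixation-like)
        folded = [fold_abs(summarize_flight(s).mean_heading) for s in stripes]
        assert np.mean(folded) < 90.0

    def test_duplicate_labels_rejected(self):
        specs = [frontal_group_spec(n_flies=1), frontal_group_spec(n_flies=1)]
        with pytest.raises(ValueError, match="duplicate group labels"):
            generate_cohort(specs, self.CFG, seed=0)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            generate_cohort([frontal_group_spec(n_flies=1)], SimConfig(duration_s=1.0))

    def test_group_spec_validation(self):
        with pytest.raises(ValueError):
            GroupSpec(label="g", n_flies=0)
        with pytest.raises(ValueError):
            GroupSpec(label="g", n_flies=1, frontal_prob=1.5)
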