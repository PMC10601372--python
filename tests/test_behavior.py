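"""Behavioral preprocessing and trial-level analytics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import levercode as lc
from levercode.behavior import (
    TrackedPoint,
    TrialAverage,
    binarize_activity,
    classify_stable_neurons,
    clean_tracking,
    detect_trials,
    remove_lever_component,
    split_velocity,
    trajectory_error,
    trial_average,
    trial_to_trial_correlation,
)

RATE = 30.0

finite_arrays = st.lists(
    st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
    min_size=1, max_size=50,
).map(np.array)


class TestSplitVelocity:
    def test_rectification(self):
        f, b = split_velocity(np.array([2.0, -3.0, 0.0]))
        assert np.array_equal(f, [2.0, 0.0, 0.0])
        assert np.array_equal(b, [0.0, 3.0, 0.0])

    @settings(derandomize=True, deadline=None)
    @given(finite_arrays)
    def test_channels_reconstruct_and_exclude(self, v):
        f, b = split_velocity(v)
        assert (f >= 0).all() and (b >= 0).all()
        assert np.array_equal(f - b, v)
        assert np.all(f * b == 0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            split_velocity(np.array([1.0, np.nan]))


class TestCleanTracking:
    def _point(self, likelihood):
        n = len(likelihood)
        return TrackedPoint(position=np.arange(n, dtype=float),
                            likelihood=np.array(likelihood))

    def test_isolated_low_frame_interpolated(self):
        pos = np.array([0.0, 5.0, 2.0])
        pt = TrackedPoint(pos, np.array([1.0, 0.5, 1.0]))
        out, bad = clean_tracking(pt, native_rate=30, target_rate=30)
        assert out[1] == pytest.approx((pos[0] + pos[2]) / 2)
        assert not bad.any()

    def test_consecutive_low_frames_omitted(self):
        pt = self._point([1, 1, 0.5, 0.5, 1, 1])
        out, bad = clean_tracking(pt, native_rate=30, target_rate=30)
        assert bad[2] and bad[3]
        assert not bad[[0, 1, 4, 5]].any()

    def test_clean_trace_is_identity_at_same_rate(self):
        pt = self._point([1.0] * 10)
        out, bad = clean_tracking(pt, native_rate=30, target_rate=30)
        assert np.allclose(out, pt.position)
        assert not bad.any()

    def test_resampling_70_to_30(self):
        n = 140
        t = np.arange(n) / 70.0
        pt = TrackedPoint(np.sin(2 * np.pi * t), np.ones(n))
        out, bad = clean_tracking(pt, native_rate=70, target_rate=30)
        tt = np.arange(len(out)) / 30.0
        assert np.allclose(out, np.sin(2 * np.pi * tt), atol=5e-3)

    def test_all_low_is_an_error(self):
        with pytest.raises(ValueError):
            clean_tracking(self._point([0.1, 0.2, 0.1]), native_rate=30, target_rate=30)


class TestRemoveLeverComponent:
    def test_exact_linear_dependence(self):
        lever = np.sin(np.linspace(0, 20, 500))
        resid, gain = remove_lever_component(2.0 * lever, lever)
        assert gain == pytest.approx(2.0)
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_orthogonal_input_untouched(self):
        rng = np.random.default_rng(0)
        lever = np.sin(np.linspace(0, 20, 500))
        rf = rng.standard_normal(500)
        rf -= (rf - rf.mean()) @ (lever - lever.mean()) / np.sum(
            (lever - lever.mean()) ** 2
        ) * lever  # orthogonalize
        resid, gain = remove_lever_component(rf, lever)
        assert gain == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(resid, rf)

    def test_gain_matches_grid_search_oracle(self):
        rng = np.random.default_rng(1)
        lever = np.cumsum(rng.standard_normal(400)) * 0.1
        rf = 1.7 * lever + rng.standard_normal(400)
        _, gain = remove_lever_component(rf, lever)
        grid = np.arange(-10.0, 10.0, 1e-4)
        sds = np.std(rf[None, :] - grid[:, None] * lever[None, :], axis=1)
        assert abs(gain - grid[np.argmin(sds)]) < 2e-4

    def test_residual_uncorrelated_with_lever(self):
        rng = np.random.default_rng(2)
        lever = np.cumsum(rng.standard_normal(300))
        rf = rng.standard_normal(300) + 0.5 * lever
        resid, _ = remove_lever_component(rf, lever)
        lc_ = lever - lever.mean()
        assert abs((resid - resid.mean()) @ lc_) < 1e-10 * (lc_ @ lc_)

    def test_constant_lever_rejected(self):
        with pytest.raises(ValueError):
            remove_lever_component(np.arange(5.0), np.ones(5))


class TestBinarize:
    def test_threshold_is_strict(self):
        out = binarize_activity(np.array([0.0, 0.005, 0.006]), 0.005)
        assert out.tolist() == [0, 0, 1]

    @settings(derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        x = np.random.default_rng(seed).uniform(0, 0.02, size=50)
        once = binarize_activity(x)
        assert np.array_equal(binarize_activity(once), once)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            binarize_activity(np.array([-0.1]))


def _pulse(duration_s, amp=4.0, start_s=3.0, total_s=10.0):
    n = int(total_s * RATE)
    lever = np.zeros(n)
    a, b = int(start_s * RATE), int((start_s + duration_s) * RATE)
    lever[a:b] = amp
    return lever


class TestDetectTrials:
    def test_long_hold_is_success(self, task_config):
        trials = detect_trials(_pulse(0.7), task_config)
        assert len(trials) == 1
        assert trials.loc[0, "outcome"] == "success"

    def test_short_hold_is_failure(self, task_config):
        trials = detect_trials(_pulse(0.5), task_config)
        assert len(trials) == 1
        assert trials.loc[0, "outcome"] == "failure"

    def test_flat_trace_gives_empty_table(self, task_config):
        trials = detect_trials(np.zeros(300), task_config)
        assert trials.empty

    def test_reward_follows_command_by_delay(self, task_config):
        trials = detect_trials(_pulse(1.0), task_config)
        d = trials.loc[0, "reward_frame"] - trials.loc[0, "command_frame"]
        assert d == round(task_config.reward_delay * RATE)

    def test_agrees_with_generator(self, small_bundle, task_config):
        redetected = detect_trials(
            small_bundle.behavior.column("lever_pos"), task_config
        )
        pd.testing.assert_frame_equal(redetected, small_bundle.trials)

    def test_every_success_satisfies_hold_rule(self, small_bundle, task_config):
        lever = small_bundle.behavior.column("lever_pos")
        hold = int(round(task_config.hold_duration * RATE))
        succ = small_bundle.trials.query("outcome == 'success'")
        for _, row in succ.iterrows():
            t0 = int(row.init_frame)
            assert (lever[t0 : t0 + hold] > task_config.pull_threshold).all()


class TestTrajectoryError:
    def test_zero_iff_identical(self):
        x = np.linspace(0, 4, 30)
        assert trajectory_error(x, x, RATE) == 0.0

    def test_constant_offset(self):
        x = np.zeros(30)
        assert trajectory_error(x + 1.0, x, RATE) == pytest.approx(1.0)

    def test_triangle_fixture_matches_direct_sum(self):
        tri = np.concatenate([np.linspace(0, 2, 9), np.linspace(2, 0, 9)])
        flat = np.full(18, 1.0)
        expected = np.abs(tri - flat).sum() / 18  # direct summation oracle
        assert trajectory_error(tri, flat, RATE) == pytest.approx(expected)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(3)
        a, b, c = rng.standard_normal((3, 18))
        ab = trajectory_error(a, b, RATE)
        assert ab == pytest.approx(trajectory_error(b, a, RATE))
        assert ab <= trajectory_error(a, c, RATE) + trajectory_error(c, b, RATE) + 1e-12

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            trajectory_error(np.zeros(5), np.zeros(5), RATE, window=0.6)


class TestTrialAverage:
    def test_single_event_returns_window(self):
        x = np.arange(300.0)
        out = trial_average(x, [100], RATE, window=(-1, 3))
        assert np.array_equal(out.mean, x[70:191])
        assert out.n_events == 1

    def test_edge_events_dropped_and_counted(self):
        x = np.arange(300.0)
        out = trial_average(x, [5, 150], RATE)
        assert out.n_events == 1 and out.n_dropped == 1

    def test_impulse_train_peaks_at_zero_lag(self):
        n = 3000
        rng = np.random.default_rng(4)
        events = np.sort(rng.choice(np.arange(100, n - 100), 20, replace=False))
        x = np.zeros(n)
        x[events] = 1.0
        out = trial_average(x, events, RATE)
        assert out.lags[np.argmax(out.mean)] == 0.0

    def test_no_usable_events_is_an_error(self):
        with pytest.raises(ValueError):
            trial_average(np.zeros(10), [5], RATE)


class TestTrialToTrialCorrelation:
    def test_identical_trials_give_one(self):
        trials = np.tile(np.sin(np.linspace(0, 6, 120)), (5, 1))
        out = trial_to_trial_correlation(trials, n_pairs=200, seed=0)
        assert out.mean_correlation == pytest.approx(1.0)
        assert out.significant

    def test_white_noise_trials_average_near_zero(self):
        rng = np.random.default_rng(5)
        trials = rng.standard_normal((40, 120))
        out = trial_to_trial_correlation(trials, n_pairs=1000, seed=1)
        assert abs(out.mean_correlation) < 3 / np.sqrt(out.n_pairs)

    def test_two_trials_all_pairs_identical(self):
        rng = np.random.default_rng(6)
        trials = rng.standard_normal((2, 120))
        out = trial_to_trial_correlation(trials, n_pairs=50, seed=2)
        expected = np.corrcoef(trials[0], trials[1])[0, 1]
        assert out.mean_correlation == pytest.approx(abs(expected) * np.sign(expected))

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            trial_to_trial_correlation(np.zeros((1, 50)))


class TestStableClassification:
    def test_identical_traces_are_stable(self):
        rng = np.random.default_rng(7)
        noise = rng.standard_normal((4, 50, 60))
        template = np.sin(np.linspace(0, 6, 60))
        traces = noise.copy()
        traces[:, 0] = template  # neuron 0 identical in all four sessions
        out = classify_stable_neurons(traces, n_shuffles=500, seed=0)
        assert out.stable[0]
        assert out.observed[0] == pytest.approx(1.0)

    def test_requires_two_sessions(self):
        with pytest.raises(ValueError):
            classify_stable_neurons(np.zeros((1, 5, 20)))

    def test_alternative_shuffle_scheme_runs(self):
        rng = np.random.default_rng(8)
        traces = rng.standard_normal((3, 20, 40))
        out = classify_stable_neurons(traces, n_shuffles=200, seed=1,
                                      scheme="circular_shift")
        assert out.stable.shape == (20,)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            classify_stable_neurons(np.zeros((2, 5, 20)) + np.arange(20),
                                    scheme="bogus")
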