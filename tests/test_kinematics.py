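import numpy as np
import pytest

import flywalk as fw
from flywalk.kinematics import (
    STATE_RUN,
    STATE_STOP,
    SegmentationError,
    classify_turns,
    turn_statistic,
)

from conftest import schmidt_oracle, score_turn_recovery, straight_trajectory


def make_traj(x, y, frame_rate=30.0, **kw):
    x = np.asarray(x, float)
    t = np.arange(len(x)) / frame_rate
    return fw.Trajectory(
        fly_id="t", times=t, x=x, y=np.asarray(y, float), frame_rate=frame_rate, **kw
    )


class TestSmoothTrack:
    def test_constant_position_unchanged(self):
        traj = make_traj(np.full(50, 1.0), np.full(50, -0.5))
        sm = fw.smooth_track(traj)
        assert np.allclose(sm.x, 1.0) and np.allclose(sm.y, -0.5)

    def test_linear_motion_unchanged_in_interior(self):
        traj = straight_trajectory(speed=0.4, n=100)
        sm = fw.smooth_track(traj, window=10)
        assert np.allclose(sm.x[10:-10], traj.x[10:-10], atol=1e-12)

    def test_noise_attenuated_by_sqrt_window(self):
        """White jitter of sd sigma on a line leaves residual sd ~
        sigma/sqrt(10) after a 10-point moving average."""
        rng = np.random.default_rng(0)
        n, sigma = 6000, 0.05
        base = straight_trajectory(speed=0.0, n=n, start=(0.0, 0.0))
        noisy = base.with_positions(
            base.x + sigma * rng.standard_normal(n), base.y
        )
        sm = fw.smooth_track(noisy, window=10)
        resid = sm.x[20:-20]
        assert np.std(resid) == pytest.approx(sigma / np.sqrt(10), rel=0.1)

    def test_record_shorter_than_window_rejected(self):
        traj = make_traj(np.zeros(5), np.zeros(5))
        with pytest.raises(SegmentationError):
            fw.smooth_track(traj, window=10)


class TestComputeKinematics:
    def test_uniform_straight_motion(self):
        traj = straight_trajectory(speed=0.5, n=100)
        kin = fw.compute_kinematics(traj)
        assert np.allclose(kin.speed, 0.5, atol=1e-9)
        assert np.allclose(kin.angular_speed[1:], 0.0, atol=1e-9)

    def test_circular_path_angular_speed(self):
        """On a circle of radius r at speed v, angular speed ~ v/r."""
        fps, r, v = 30.0, 1.0, 0.5
        n = 400
        t = np.arange(n) / fps
        theta = v / r * t
        traj = make_traj(r * np.cos(theta), r * np.sin(theta), frame_rate=fps)
        kin = fw.compute_kinematics(traj)
        assert np.nanmedian(np.abs(kin.angular_speed)) == pytest.approx(v / r, rel=0.02)

    def test_slow_frames_masked(self):
        traj = straight_trajectory(speed=0.1, n=60)  # below the 2 mm/s floor
        kin = fw.compute_kinematics(traj)
        assert np.isnan(kin.angular_speed).all()
        assert (~kin.valid).all()

    def test_too_short_record_rejected(self):
        with pytest.raises(SegmentationError):
            fw.compute_kinematics(make_traj([0, 0.1], [0, 0]))


class TestSchmidtTrigger:
    def test_constant_slow_speed_single_stop(self):
        seg = fw.segment_runs_stops(np.full(100, 0.03))
        assert (seg.states == STATE_STOP).all()
        assert len(seg.stop_episodes) == 1
        assert seg.stop_episodes.iloc[0]["duration_s"] == pytest.approx(100 / 30)

    def test_dead_band_continues_previous_state(self):
        speeds = np.array([0.2, 0.2, 0.07, 0.07, 0.2])
        seg = fw.segment_runs_stops(speeds)
        assert (seg.states == STATE_RUN).all()
        assert len(seg.run_episodes) == 1

    def test_leading_dead_band_backfilled(self):
        speeds = np.array([0.07, 0.07, 0.03, 0.2])
        states = fw.schmidt_states(speeds)
        assert list(states) == [STATE_STOP] * 3 + [STATE_RUN]

    def test_all_dead_band_rejected(self):
        with pytest.raises(SegmentationError):
            fw.schmidt_states(np.full(10, 0.07))

    def test_matches_bruteforce_oracle_on_random_traces(self):
        """10^4 random three-level speed traces produce identical labels to
        an independent per-frame state machine."""
        rng = np.random.default_rng(42)
        levels = np.array([0.03, 0.07, 0.2])  # stop / dead band / run
        for _ in range(200):
            n = rng.integers(2, 60)
            speeds = levels[rng.integers(0, 3, n)]
            if np.all(speeds == 0.07):
                continue
            expected = schmidt_oracle(speeds)
            got = fw.schmidt_states(speeds)
            assert list(got) == expected
        # plus a vectorized batch against the oracle
        batch = levels[rng.integers(0, 3, size=(10_000, 12))]
        batch[:, 0] = 0.2  # guarantee a decisive frame per row
        got = fw.schmidt_states(batch)
        for row_speed, row_state in zip(batch[:500], got[:500]):
            assert list(row_state) == schmidt_oracle(row_speed)


class TestClassifyTurns:
    def test_straight_walk_no_turns(self):
        labels, events = classify_turns(np.zeros(100), frame_rate=30.0)
        assert (labels == 0).all()
        assert len(events) == 0

    def test_injected_sharp_window_gives_one_event(self):
        """Five frames of signed angular displacement summing to 1.5 rad
        (> 1.3) yield exactly one sharp-turn event."""
        fps = 30.0
        ang = np.zeros(60)
        ang[30:35] = 0.3 * fps  # displacement 0.3 rad per frame
        labels, events = classify_turns(ang, frame_rate=fps)
        assert len(events) == 1
        assert events.iloc[0]["magnitude"] == pytest.approx(1.5, abs=1e-9)

    def test_smooth_turn_between_thresholds(self):
        fps = 30.0
        ang = np.zeros(60)
        ang[30:35] = 0.1 * fps  # sum 0.5 rad: turning but not sharp
        labels, events = classify_turns(ang, frame_rate=fps)
        assert (labels[30:40] == 1).any()
        assert len(events) == 0

    def test_left_right_symmetric(self):
        fps = 30.0
        ang = np.zeros(60)
        ang[30:35] = 0.3 * fps
        l1, e1 = classify_turns(ang, frame_rate=fps)
        l2, e2 = classify_turns(-ang, frame_rate=fps)
        assert np.array_equal(l1, l2)
        assert e2.iloc[0]["magnitude"] == pytest.approx(-1.5, abs=1e-9)

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(SegmentationError):
            turn_statistic(np.zeros(3), 30.0, window=5)

    def test_rotation_invariance(self, null_config):
        """Turn labels are unchanged under a global rotation of the
        trajectory."""
        traj, _ = fw.simulate_fly(
            fw.null_walker_config(duration_before=30, duration_during=30), seed=3
        )
        _sm, _kin, seg = fw.segment(traj)
        c, s = np.cos(1.1), np.sin(1.1)
        rot = traj.with_positions(c * traj.x - s * traj.y, s * traj.x + c * traj.y)
        _sm2, _kin2, seg2 = fw.segment(rot)
        assert np.array_equal(seg.turn_labels, seg2.turn_labels)

    def test_event_recovery_on_synthetic_cohort(self, null_config):
        """Sharp-turn events at the generator's default turn angle are
        recovered from rendered kinematics with high recall and precision
        (scored away from wall contacts, which turn the path without a
        discrete event)."""
        recall, precision = score_turn_recovery(null_config, range(5))
        assert recall >= 0.95
        assert precision >= 0.95


class TestEpochs:
    def _traj_inside_at(self, r_at_odor_on, enter_at=None):
        fps, n = 30.0, 30 * 360
        t = np.arange(n) / fps
        r = np.full(n, r_at_odor_on)
        if enter_at is not None:
            r[: int(enter_at * fps)] = 2.5
            r[int(enter_at * fps) :] = 0.5
        return fw.Trajectory(
            fly_id="e", times=t, x=r, y=np.zeros(n), frame_rate=fps
        )

    def test_inside_at_odor_on_starts_after_latency(self):
        traj = self._traj_inside_at(0.5)
        ep = fw.delineate_epochs(traj)
        assert ep.before == (0.0, 180.0)
        assert ep.during == (185.0, 360.0)

    def test_outside_at_odor_on_starts_at_first_entry(self):
        traj = self._traj_inside_at(2.5, enter_at=200.0)
        ep = fw.delineate_epochs(traj)
        assert ep.during[0] == pytest.approx(200.0, abs=1 / 30)
        assert ep.during[1] == pytest.approx(360.0)

    def test_never_entering_fly_excluded(self):
        traj = self._traj_inside_at(2.5)
        ep = fw.delineate_epochs(traj)
        assert ep.excluded
        assert "never entered" in ep.exclusion_reason

    def test_epochs_partition_record(self):
        fps, n = 30.0, 30 * 420  # 7 min record -> non-empty after period
        t = np.arange(n) / fps
        traj = fw.Trajectory(
            fly_id="e", times=t, x=np.full(n, 0.5), y=np.zeros(n), frame_rate=fps
        )
        ep = fw.delineate_epochs(traj)
        assert ep.before[1] == 180.0
        assert ep.during == (185.0, 360.0)
        assert ep.after == (360.0, pytest.approx(420.0, abs=1 / 30))


class TestTransits:
    def test_single_crossing_single_open_transit(self):
        fps = 30.0
        n = 120
        t = np.arange(n) / fps
        x = np.linspace(3.0, 0.2, n)  # monotone approach through boundary
        traj = fw.Trajectory(fly_id="t", times=t, x=x, y=np.zeros(n), frame_rate=fps)
        transits, outside = fw.detect_transits(traj)
        assert len(transits) == 1
        assert not transits.iloc[0]["complete"]

    def test_single_frame_touch_debounced(self):
        fps = 30.0
        r = np.full(60, 2.0)
        r[30] = 1.1  # one-frame dip inside
        traj = fw.Trajectory(
            fly_id="t", times=np.arange(60) / fps, x=r, y=np.zeros(60), frame_rate=fps
        )
        transits, _ = fw.detect_transits(traj, debounce=2)
        assert len(transits) == 0

    def test_crossing_times_match_ground_truth(self, null_config):
        """Detected entries fall within one frame of the simulator's own
        zone-entry frames (after the same debouncing)."""
        traj, truth = fw.simulate_fly(null_config, seed=6)
        transits, _ = fw.detect_transits(traj, debounce=1)
        inside_truth = (truth.context % 2) == 1
        true_entries = np.flatnonzero(np.diff(inside_truth.astype(int)) == 1) + 1
        det_entries = transits["entry_frame"].to_numpy()
        det_entries = det_entries[det_entries > 0]
        for f in det_entries:
            assert np.min(np.abs(true_entries - f)) <= 1

    def test_boundary_must_be_inside_arena(self, null_config):
        traj, _ = fw.simulate_fly(
            fw.null_walker_config(duration_before=10, duration_during=10), seed=1
        )
        with pytest.raises(ValueError):
            fw.detect_transits(traj, boundary_radius=5.0)
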