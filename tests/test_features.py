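import numpy as np
import pytest

import flywalk as fw
from flywalk.features import FEATURE_NAMES
from flywalk.kinematics import EpochSet


class TestFeatureVector:
    def test_exactly_17_named_parameters(self):
        assert len(FEATURE_NAMES) == 17
        fv = fw.FeatureVector(fly_id="f")
        assert set(fv.values) == set(FEATURE_NAMES)
        assert len(fv.to_series()) == 17

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            fw.FeatureVector(fly_id="f", values={"bogus": 1.0})

    def test_attraction_index_matches_occupancy_change(self):
        """A 2.5-fold increase in fractional time inside the odor zone is an
        attraction index of 1.5, and the pipeline reproduces the analytic
        occupancy arithmetic on a constructed trajectory."""
        # the defining identity: 60 s of 180 before vs 150 s of 180 during
        assert (150 / 180 - 60 / 180) / (60 / 180) == pytest.approx(1.5)

        fps = 30.0
        n = int(360 * fps)
        t = np.arange(n) / fps
        r = np.full(n, 2.5)
        # before period: inside [0, 50) and [170, 180) = 60 s total; inside
        # well before odor on, so 'during' = [185, 360) with 150 s inside
        r[: int(50 * fps)] = 0.5
        r[int(170 * fps) : int(335 * fps)] = 0.5
        traj = fw.Trajectory(
            fly_id="a", times=t, x=r, y=np.zeros(n), frame_rate=fps
        )
        fv = fw.extract_features(traj)
        # 60 s inside before vs 150 s inside in the during epoch [185, 360)
        assert fv.values["attraction_index"] == pytest.approx(1.5, abs=0.05)

    def test_null_walker_parameters_center_on_identity(self, null_config):
        """Identical before/during behavior: normalized changes ~ 0 and
        ratios ~ 1 at the cohort level."""
        vecs = []
        for traj, _ in fw.simulate_cohort(null_config, 30, seed=2):
            fv = fw.extract_features(traj)
            if not fv.excluded:
                vecs.append(fv)
        table = fw.feature_table(vecs)
        change_params = [
            "attraction_index",
            "speed_inside",
            "speed_outside",
            "angular_speed_inside",
            "angular_speed_outside",
        ]
        ratio_params = [
            "run_duration_ratio",
            "stop_duration_ratio",
            "run_probability_in",
            "run_probability_out",
        ]
        rng = np.random.default_rng(0)
        for name, center in [(p, 0.0) for p in change_params] + [
            (p, 1.0) for p in ratio_params
        ]:
            vals = table[name].dropna().to_numpy()
            boots = np.median(
                rng.choice(vals, size=(2000, len(vals)), replace=True), axis=1
            )
            lo, hi = np.percentile(boots, [1, 99])
            assert lo <= center <= hi, (name, lo, hi)

    def test_fold_change_recovery(self):
        """A generator with during run duration at half the before median
        yields run_duration_ratio ~ 0.5."""
        import dataclasses

        base = fw.ContextParams()
        dur = dataclasses.replace(base, median_run_duration=base.median_run_duration / 2)
        cfg = fw.WalkerConfig(during_inside=dur, during_outside=dur)
        vals = [
            fw.extract_features(t).values["run_duration_ratio"]
            for t, _ in fw.simulate_cohort(cfg, 30, seed=4)
        ]
        assert np.nanmedian(vals) == pytest.approx(0.5, rel=0.15)

    def test_excluded_fly_all_undefined(self, null_config):
        fps = 30.0
        n = int(360 * fps)
        t = np.arange(n) / fps
        traj = fw.Trajectory(
            fly_id="out", times=t, x=np.full(n, 2.5), y=np.zeros(n), frame_rate=fps
        )
        fv = fw.extract_features(traj)
        assert fv.excluded
        assert all(np.isnan(v) for v in fv.values.values())

    def test_turn_fractions_bounded(self, acv_config):
        for traj, _ in fw.simulate_cohort(acv_config, 5, seed=8):
            fv = fw.extract_features(traj)
            if fv.excluded:
                continue
            for name in ("smooth_turns_in", "smooth_turns_out", "sharp_turns_at_boundary"):
                v = fv.values[name]
                if np.isfinite(v):
                    assert 0.0 <= v <= 1.0


class TestProfiles:
    def test_uniform_disc_gives_flat_radial_profile(self):
        rng = np.random.default_rng(1)
        n = 200_000
        r = 3.2 * np.sqrt(rng.random(n))
        th = rng.random(n) * 2 * np.pi
        traj = fw.Trajectory(
            fly_id="u",
            times=np.arange(n) / 30.0,
            x=r * np.cos(th),
            y=r * np.sin(th),
            frame_rate=30.0,
        )
        prof = fw.radial_density_profile(traj)
        assert len(prof.values) == 12
        assert prof.values.std() / prof.values.mean() < 0.05
        # area-weighted values integrate to total occupancy
        areas = np.pi * np.diff(prof.bin_edges**2)
        assert (prof.values * areas).sum() == pytest.approx(1.0)

    def test_single_radius_single_bin(self):
        n = 100
        traj = fw.Trajectory(
            fly_id="s",
            times=np.arange(n) / 30.0,
            x=np.full(n, 1.5),
            y=np.zeros(n),
            frame_rate=30.0,
        )
        prof = fw.radial_density_profile(traj)
        assert (prof.values > 0).sum() == 1

    def test_wall_attracted_walker_peaks_at_edge(self, null_config):
        traj, _ = fw.simulate_fly(null_config, seed=3)
        prof = fw.radial_density_profile(traj, interval=(0.0, 180.0))
        assert np.argmax(prof.values) >= 9  # outermost quarter of 12 bins

    def test_crossing_trace_zero_for_identical_periods(self, null_config):
        """Cohort-averaged during − before crossing traces fluctuate around
        zero when the odor changes nothing (per-fly traces are few-crossing
        averages and individually noisy)."""
        traces = []
        for traj, _ in fw.simulate_cohort(null_config, 12, seed=9):
            sm, kin, _seg = fw.segment(traj)
            ep = fw.delineate_epochs(sm)
            if ep.during is None:
                continue
            try:
                prof = fw.crossing_speed_trace(sm, kin, ep, direction="in")
            except ValueError:
                continue
            traces.append(prof.values)
        mean_trace = np.nanmean(np.stack(traces), axis=0)
        assert np.abs(np.nanmean(mean_trace)) < 0.06

    def test_crossing_trace_negative_when_fly_slows_inside(self):
        """A walker that halves run speed inside during odor shows a
        negative entry-aligned speed difference after t = 0."""
        import dataclasses

        slow = dataclasses.replace(fw.ContextParams(), median_run_speed=0.28)
        cfg = fw.WalkerConfig(
            during_inside=slow, during_outside=fw.ContextParams()
        )
        diffs = []
        for traj, _ in fw.simulate_cohort(cfg, 10, seed=12):
            sm, kin, _seg = fw.segment(traj)
            ep = fw.delineate_epochs(sm)
            if ep.during is None:
                continue
            try:
                prof = fw.crossing_speed_trace(sm, kin, ep, direction="in")
            except ValueError:
                continue
            centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
            diffs.append(np.nanmean(prof.values[centers > 0.5]))
        assert np.nanmean(diffs) < -0.05

    def test_occupancy_time_course(self, null_config):
        n = 300
        t = np.arange(n) / 30.0
        all_inside = fw.Trajectory(
            fly_id="i", times=t, x=np.full(n, 0.3), y=np.zeros(n), frame_rate=30.0
        )
        prof = fw.occupancy_time_course([all_inside], bin_s=2.0)
        assert np.allclose(prof.values, 1.0)
        with pytest.raises(ValueError):
            fw.occupancy_time_course([])

    def test_null_cohort_occupancy_near_area_fraction(self, null_config):
        """Without odor modulation but with wall attraction, zone occupancy
        stays below the geometric area fraction; with wall attraction off it
        approaches it."""
        import dataclasses

        free = dataclasses.replace(fw.ContextParams(), wall_attraction=0.0)
        cfg = fw.WalkerConfig(
            duration_before=90.0,
            duration_during=90.0,
            before_inside=free,
            before_outside=free,
            during_inside=free,
            during_outside=free,
        )
        trajs = [t for t, _ in fw.simulate_cohort(cfg, 20, seed=3)]
        prof = fw.occupancy_time_course(trajs, bin_s=30.0)
        area_frac = (1.2 / 3.2) ** 2
        assert prof.values.mean() == pytest.approx(area_frac, abs=0.08)

    def test_point_source_profile_constant_speed(self):
        from scipy.signal import sawtooth

        n = 3000
        t = np.arange(n) / 30.0
        # constant-speed radial zig-zag between 0.3 and 4.7 cm
        arena = fw.ArenaGeometry(arena_radius=5.0, odor_zone_radius=1.0)
        x = 2.5 + 2.2 * sawtooth(2 * np.pi * t / 40.0, width=0.5)
        traj = fw.Trajectory(
            fly_id="p",
            times=t,
            x=x,
            y=np.zeros(n),
            frame_rate=30.0,
            arena=arena,
        )
        sm = fw.smooth_track(traj)
        kin = fw.compute_kinematics(sm)
        prof = fw.point_source_radial_speed(sm, kin)
        visited = np.isfinite(prof.values)
        # speed profile is max-normalized; a near-constant-speed path gives
        # values close to 1 in all visited bins
        assert prof.values[visited].min() > 0.6
        assert np.nanmax(prof.values) == pytest.approx(1.0)

    def test_point_source_single_bin_visit(self):
        n = 100
        arena = fw.ArenaGeometry(arena_radius=5.0, odor_zone_radius=1.0)
        t = np.arange(n) / 30.0
        traj = fw.Trajectory(
            fly_id="p",
            times=t,
            x=2.25 + 0.01 * np.sin(t),
            y=np.zeros(n),
            frame_rate=30.0,
            arena=arena,
        )
        kin = fw.compute_kinematics(traj)
        prof = fw.point_source_radial_speed(traj, kin)
        assert np.isfinite(prof.values).sum() == 1


class TestFeatureTable:
    def test_table_shape_and_columns(self, short_null_config):
        vecs = [
            fw.extract_features(
                t,
                fw.PipelineConfig(odor_on=60.0, odor_latency=5.0),
            )
            for t, _ in fw.simulate_cohort(short_null_config, 3, seed=1)
        ]
        table = fw.feature_table(vecs)
        assert list(table.columns[3:]) == FEATURE_NAMES
        assert len(table) == 3
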