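"""Per-fly motor parameters and auxiliary behavioral profiles.

The 17-parameter description of a fly's odor response covers position (4),
speed (4), run/stop statistics (4) and turning (5). Change-type parameters
are normalized changes (during − before)/before so that each fly is its own
control; run/stop statistics are during/before ratios; turn fractions are
computed on the during period alone. Parameters whose before-period
denominator is zero or whose required events are absent are NaN with a
recorded reason — never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .kinematics import (
    STATE_RUN,
    TURN_SHARP,
    TURN_SMOOTH,
    EpochSet,
    KinematicSeries,
    SegmentLabeling,
    delineate_epochs,
    detect_transits,
    segment,
)
from .trajectory import Trajectory

FEATURE_NAMES = [
    "attraction_index",
    "time_inside_per_transit",
    "time_to_return",
    "radial_density_shift",
    "speed_inside",
    "speed_outside",
    "speed_crossing_inside",
    "speed_crossing_outside",
    "run_duration_ratio",
    "stop_duration_ratio",
    "run_probability_in",
    "run_probability_out",
    "angular_speed_inside",
    "angular_speed_outside",
    "smooth_turns_in",
    "smooth_turns_out",
    "sharp_turns_at_boundary",
]


@dataclass
class Profile:
    """A binned profile (radial density, speed trace, time course)."""

    bin_edges: np.ndarray
    values: np.ndarray
    normalization: str
    n: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.values = np.asarray(self.values, float)
        if len(self.values) != len(self.bin_edges) - 1:
            raise ValueError("values length must equal number of bins")


@dataclass
class FeatureVector:
    """The 17 named motor parameters for one fly, plus metadata."""

    fly_id: str
    group: str = ""
    values: dict[str, float] = field(default_factory=dict)
    excluded: bool = False
    reasons: dict[str, str] = field(default_factory=dict)
    radial_profile_before: Profile | None = None
    radial_profile_during: Profile | None = None

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            self.values.setdefault(name, np.nan)
        extra = set(self.values) - set(FEATURE_NAMES)
        if extra:
            raise ValueError(f"unknown parameters: {sorted(extra)}")

    def to_series(self) -> pd.Series:
        return pd.Series({name: self.values[name] for name in FEATURE_NAMES})


def _norm_change(during: float, before: float) -> float:
    """(during − before)/before; NaN when the baseline is zero/undefined."""
    if not np.isfinite(before) or before == 0 or not np.isfinite(during):
        return np.nan
    return (during - before) / before


def _ratio(during: float, before: float) -> float:
    if not np.isfinite(before) or before == 0 or not np.isfinite(during):
        return np.nan
    return during / before


def _frames_in(traj: Trajectory, interval: tuple[float, float]) -> np.ndarray:
    return (traj.times >= interval[0]) & (traj.times < interval[1])


def _slice_trajectory(traj: Trajectory, interval: tuple[float, float]) -> Trajectory:
    mask = _frames_in(traj, interval)
    idx = np.flatnonzero(mask)
    sub = Trajectory(
        fly_id=traj.fly_id,
        times=traj.times[idx] - traj.times[idx[0]],
        x=traj.x[idx],
        y=traj.y[idx],
        frame_rate=traj.frame_rate,
        arena=traj.arena,
        flagged=np.asarray(traj.flagged)[idx],
    )
    return sub


def _median_transit_stats(
    traj: Trajectory, interval: tuple[float, float], debounce: int
) -> tuple[float, float]:
    """(median dwell inside per transit, median time outside between
    transits), in s, within one epoch; NaN when there are no complete
    intervals of that kind."""
    sub = _slice_trajectory(traj, interval)
    transits, outside = detect_transits(sub, debounce=debounce)

    def med(df: pd.DataFrame) -> float:
        comp = df[df["complete"]] if df["complete"].any() else df
        return float(comp["dwell_s"].median()) if len(comp) else np.nan

    return med(transits), med(outside)


def _median_episode_duration(
    seg: SegmentLabeling, episodes: pd.DataFrame, frame_interval: tuple[int, int]
) -> float:
    """Median duration of episodes clipped to a half-open frame interval."""
    a, b = frame_interval
    start = episodes["start"].clip(lower=a)
    end = episodes["end"].clip(upper=b)
    keep = end > start
    if not keep.any():
        return np.nan
    return float(((end - start)[keep] / seg.frame_rate).median())


def _crossing_mean_speed(
    traj: Trajectory,
    kin: KinematicSeries,
    interval: tuple[float, float],
    direction: str,
    window: tuple[float, float],
    debounce: int,
) -> float:
    """Mean of per-crossing mean speeds in a time window after crossings of
    the odor-zone boundary within one epoch."""
    mask = _frames_in(traj, interval)
    offset = int(np.flatnonzero(mask)[0])
    sub = _slice_trajectory(traj, interval)
    transits, outside = detect_transits(sub, debounce=debounce)
    if direction == "in":
        frames = transits["entry_frame"].to_numpy()
        frames = frames[frames > 0]  # a period starting inside is not a crossing
    else:
        frames = outside["entry_frame"].to_numpy()
        frames = frames[frames > 0]
    if len(frames) == 0:
        return np.nan
    fps = traj.frame_rate
    lo = int(round(window[0] * fps))
    hi = int(round(window[1] * fps))
    per_crossing = []
    n_period = len(sub)
    for f in frames:
        a, b = f + lo, min(f + hi, n_period)
        if b <= a:
            continue
        per_crossing.append(np.nanmean(kin.speed[offset + a : offset + b]))
    return float(np.mean(per_crossing)) if per_crossing else np.nan


def radial_density_profile(
    traj: Trajectory,
    interval: tuple[float, float] | None = None,
    n_bins: int = 12,
) -> Profile:
    """Occupancy per equal-width radial bin, normalized by annulus area.

    Uniform occupancy of the disc gives a flat profile; values integrate
    (sum of value * area) to the total occupancy fraction (1.0).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    r = traj.radius
    if interval is not None:
        r = r[_frames_in(traj, interval)]
    if len(r) == 0:
        raise ValueError("epoch contains no frames")
    edges = np.linspace(0.0, traj.arena.arena_radius, n_bins + 1)
    counts, _ = np.histogram(np.clip(r, 0, edges[-1] - 1e-12), bins=edges)
    frac = counts / counts.sum()
    areas = np.pi * np.diff(edges**2)
    return Profile(
        bin_edges=edges,
        values=frac / areas,
        normalization="area-normalized",
        n=len(r),
    )


def crossing_speed_trace(
    traj: Trajectory,
    kin: KinematicSeries,
    epochs: EpochSet,
    direction: str = "in",
    bin_s: float = 0.16,
    window: tuple[float, float] = (-3.0, 3.0),
    debounce: int = 2,
) -> Profile:
    """Before-subtracted crossing-aligned speed trace (during − before).

    Crossings of the odor-zone boundary in each period are aligned at t = 0;
    per-period mean traces are binned (default 160 ms ≈ 5 frames) and the
    during trace minus the before trace is returned.
    """
    if epochs.during is None:
        raise ValueError(f"no during epoch: {epochs.exclusion_reason}")
    fps = traj.frame_rate
    lo, hi = int(round(window[0] * fps)), int(round(window[1] * fps))
    rel = np.arange(lo, hi)

    def period_trace(interval: tuple[float, float]) -> np.ndarray:
        mask = _frames_in(traj, interval)
        offset = int(np.flatnonzero(mask)[0])
        sub = _slice_trajectory(traj, interval)
        transits, outside = detect_transits(sub, debounce=debounce)
        src = transits if direction == "in" else outside
        frames = src["entry_frame"].to_numpy()
        frames = frames[frames > 0]
        if len(frames) == 0:
            raise ValueError(f"no {direction}-crossings in period {interval}")
        acc = np.full((len(frames), len(rel)), np.nan)
        for k, f in enumerate(frames):
            sel = offset + f + rel
            ok = (sel >= 0) & (sel < len(kin.speed))
            acc[k, ok] = kin.speed[sel[ok]]
        return np.nanmean(acc, axis=0)

    before = period_trace(epochs.before)
    during = period_trace(epochs.during)
    per_bin = max(1, int(round(bin_s * fps)))
    n_bins = len(rel) // per_bin
    cut = n_bins * per_bin

    def binned(tr: np.ndarray) -> np.ndarray:
        return np.nanmean(tr[:cut].reshape(n_bins, per_bin), axis=1)

    edges = window[0] + np.arange(n_bins + 1) * per_bin / fps
    return Profile(
        bin_edges=edges,
        values=binned(during) - binned(before),
        normalization="before-subtracted",
        n=1,
    )


def occupancy_time_course(
    trajs: list[Trajectory], bin_s: float = 5.0
) -> Profile:
    """Fraction of flies inside the odor zone per time bin across the trial."""
    if not trajs:
        raise ValueError("empty cohort")
    t_end = min(float(t.times[-1]) for t in trajs)
    edges = np.arange(0.0, t_end + bin_s, bin_s)
    if edges[-1] > t_end + 1e-9:
        edges = edges[:-1]
    vals = np.zeros(len(edges) - 1)
    for k in range(len(edges) - 1):
        frac = [
            float(np.mean(t.inside_zone()[_frames_in(t, (edges[k], edges[k + 1]))]))
            for t in trajs
        ]
        vals[k] = float(np.mean(frac))
    return Profile(bin_edges=edges, values=vals, normalization="fraction", n=len(trajs))


def transit_time_course(
    trajs: list[Trajectory],
    bin_s: float = 15.0,
    statistic: str = "dwell",
    debounce: int = 2,
) -> Profile:
    """Median time inside per transit ('dwell') or time to return ('return')
    versus time since trial start, pooled over flies in 15 s bins."""
    if not trajs:
        raise ValueError("empty cohort")
    t_end = min(float(t.times[-1]) for t in trajs)
    edges = np.arange(0.0, t_end + bin_s, bin_s)
    entries: list[float] = []
    dwells: list[float] = []
    for t in trajs:
        transits, outside = detect_transits(t, debounce=debounce)
        src = transits if statistic == "dwell" else outside
        src = src[src["complete"]]
        entries.extend(src["entry_time"])
        dwells.extend(src["dwell_s"])
    entries_a = np.asarray(entries)
    dwells_a = np.asarray(dwells)
    vals = np.full(len(edges) - 1, np.nan)
    for k in range(len(edges) - 1):
        sel = (entries_a >= edges[k]) & (entries_a < edges[k + 1])
        if sel.any():
            vals[k] = float(np.median(dwells_a[sel]))
    return Profile(bin_edges=edges, values=vals, normalization="median-s", n=len(trajs))


def point_source_radial_speed(
    traj: Trajectory, kin: KinematicSeries, n_bins: int = 10
) -> Profile:
    """Mean speed per concentric radial bin, max-normalized per fly.

    For the point-source assay (10 cm arena, odor port at the center): bins
    never visited are NaN and excluded from cohort averaging.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0.0, traj.arena.arena_radius, n_bins + 1)
    which = np.digitize(traj.radius, edges[1:-1])
    vals = np.full(n_bins, np.nan)
    for k in range(n_bins):
        sel = which == k
        if sel.any():
            vals[k] = float(np.nanmean(kin.speed[sel]))
    vmax = np.nanmax(vals)
    if np.isfinite(vmax) and vmax > 0:
        vals = vals / vmax
    return Profile(bin_edges=edges, values=vals, normalization="max-normalized", n=1)


def compute_feature_vector(
    traj: Trajectory,
    kin: KinematicSeries,
    seg: SegmentLabeling,
    epochs: EpochSet,
    config: PipelineConfig | None = None,
    group: str = "",
) -> FeatureVector:
    """All 17 motor parameters for one fly.

    ``traj`` must be the smoothed trajectory the kinematics were computed
    from; ``seg`` must carry turn labels and sharp-turn events.
    """
    config = config or PipelineConfig()
    fv = FeatureVector(fly_id=traj.fly_id, group=group)
    if epochs.during is None:
        fv.excluded = True
        fv.reasons["all"] = epochs.exclusion_reason or "no during epoch"
        return fv

    inside = traj.inside_zone()
    run = np.asarray(seg.states) == STATE_RUN
    vals = fv.values
    periods = {"before": epochs.before, "during": epochs.during}
    per: dict[str, dict[str, float]] = {}
    for name, interval in periods.items():
        m = _frames_in(traj, interval)
        m_in = m & inside
        m_out = m & ~inside
        dwell, ret = _median_transit_stats(traj, interval, config.transit_debounce)
        f0 = int(np.flatnonzero(m)[0])
        f1 = int(np.flatnonzero(m)[-1]) + 1
        per[name] = {
            # raw time inside (s): with the entry-conditioned during start,
            # raw time self-cancels the guaranteed entry dwell against the
            # shortened period under the null; fractional occupancy does not
            "time_inside": float(np.sum(inside[m])) / traj.frame_rate,
            "mean_r": float(np.mean(traj.radius[m])),
            "dwell": dwell,
            "return": ret,
            "speed_in": float(np.mean(kin.speed[m_in])) if m_in.any() else np.nan,
            "speed_out": float(np.mean(kin.speed[m_out])) if m_out.any() else np.nan,
            "cross_in": _crossing_mean_speed(
                traj, kin, interval, "in", (1.0, 2.0), config.transit_debounce
            ),
            "cross_out": _crossing_mean_speed(
                traj, kin, interval, "out", (1.0, 2.0), config.transit_debounce
            ),
            "run_med": _median_episode_duration(seg, seg.run_episodes, (f0, f1)),
            "stop_med": _median_episode_duration(seg, seg.stop_episodes, (f0, f1)),
            "p_run_in": float(np.mean(run[m_in])) if m_in.any() else np.nan,
            "p_run_out": float(np.mean(run[m_out])) if m_out.any() else np.nan,
            "ang_in": (
                float(np.nanmean(np.abs(kin.angular_speed[m_in])))
                if np.isfinite(kin.angular_speed[m_in]).any()
                else np.nan
            ),
            "ang_out": (
                float(np.nanmean(np.abs(kin.angular_speed[m_out])))
                if np.isfinite(kin.angular_speed[m_out]).any()
                else np.nan
            ),
        }

    b, d = per["before"], per["during"]
    vals["attraction_index"] = _norm_change(d["time_inside"], b["time_inside"])
    vals["time_inside_per_transit"] = _norm_change(d["dwell"], b["dwell"])
    vals["time_to_return"] = _norm_change(d["return"], b["return"])
    vals["radial_density_shift"] = _norm_change(d["mean_r"], b["mean_r"])
    vals["speed_inside"] = _norm_change(d["speed_in"], b["speed_in"])
    vals["speed_outside"] = _norm_change(d["speed_out"], b["speed_out"])
    vals["speed_crossing_inside"] = _norm_change(d["cross_in"], b["cross_in"])
    vals["speed_crossing_outside"] = _norm_change(d["cross_out"], b["cross_out"])
    vals["run_duration_ratio"] = _ratio(d["run_med"], b["run_med"])
    vals["stop_duration_ratio"] = _ratio(d["stop_med"], b["stop_med"])
    vals["run_probability_in"] = _ratio(d["p_run_in"], b["p_run_in"])
    vals["run_probability_out"] = _ratio(d["p_run_out"], b["p_run_out"])
    vals["angular_speed_inside"] = _norm_change(d["ang_in"], b["ang_in"])
    vals["angular_speed_outside"] = _norm_change(d["ang_out"], b["ang_out"])

    # turn fractions: during period only
    m_during = _frames_in(traj, epochs.during)
    labels = seg.turn_labels
    if labels is not None:
        for suffix, zone_mask in (("in", inside), ("out", ~inside)):
            denom = int(np.sum(run & m_during & zone_mask))
            if denom > 0:
                numer = int(
                    np.sum((labels == TURN_SMOOTH) & m_during & zone_mask)
                )
                vals[f"smooth_turns_{suffix}"] = numer / denom
            else:
                fv.reasons[f"smooth_turns_{suffix}"] = "no run frames in zone"
    events = seg.sharp_turn_events
    if events is not None and len(events):
        t0, t1 = epochs.during
        sel = events[(events["time"] >= t0) & (events["time"] < t1)]
        if len(sel):
            r = np.hypot(sel["x"].to_numpy(), sel["y"].to_numpy())
            ring = (
                np.abs(r - traj.arena.odor_boundary_radius)
                <= traj.arena.turn_ring_halfwidth
            )
            vals["sharp_turns_at_boundary"] = float(np.mean(ring))
        else:
            fv.reasons["sharp_turns_at_boundary"] = "no sharp turns in during period"
    else:
        fv.reasons["sharp_turns_at_boundary"] = "no sharp turns detected"

    for name in FEATURE_NAMES:
        if not np.isfinite(vals[name]) and name not in fv.reasons:
            fv.reasons[name] = "undefined (zero or missing baseline)"

    fv.radial_profile_before = radial_density_profile(traj, epochs.before)
    fv.radial_profile_during = radial_density_profile(traj, epochs.during)
    return fv


def extract_features(
    traj: Trajectory, config: PipelineConfig | None = None, group: str = ""
) -> FeatureVector:
    """One-call pipeline for a single fly: smooth → kinematics → segment →
    epochs → the 17 parameters."""
    config = config or PipelineConfig()
    smoothed, kin, seg = segment(
        traj,
        smoothing_window=config.smoothing_window,
        stop_threshold=config.stop_threshold,
        run_threshold=config.run_threshold,
        min_speed_for_angular=config.min_speed_for_angular,
        turn_window=config.turn_window,
        smooth_turn_threshold=config.smooth_turn_threshold,
        sharp_turn_threshold=config.sharp_turn_threshold,
    )
    epochs = delineate_epochs(smoothed, config.odor_on, config.odor_latency)
    return compute_feature_vector(smoothed, kin, seg, epochs, config, group=group)


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Flies × 17 parameter table with fly_id/group/excluded metadata."""
    rows = []
    for fv in vectors:
        row = {"fly_id": fv.fly_id, "group": fv.group, "excluded": fv.excluded}
        row.update({name: fv.values[name] for name in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=["fly_id", "group", "excluded"] + FEATURE_NAMES)
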