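"""Track smoothing, speed/angular-speed series, and segmentation of
locomotion into runs, stops, smooth turns and sharp turns.

The segmentation follows the assay's published recipe: positions are boxcar
smoothed over 10 frames; speed is the displacement between consecutive
smoothed frames divided by the frame interval; runs and stops are assigned
by a Schmidt trigger (two-threshold hysteresis: below 0.05 cm/s = stop,
above 0.1 cm/s = run, in between continues the previous state); turning is
scored from the net angular displacement over a sliding 5-frame window,
with > 0.3 rad marking a turn and > 1.3 rad a sharp turn. Angular speed is
disregarded below 2 mm/s; those frames are bridged (the heading carries over)
so that slow mid-turn frames do not erase net rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory


class SegmentationError(ValueError):
    pass


@dataclass
class KinematicSeries:
    """Per-frame speed (cm/s), heading (rad) and signed angular speed
    (rad/s). ``angular_speed`` is NaN where speed < the validity floor;
    ``heading`` is always defined (carried over slow frames)."""

    speed: np.ndarray
    heading: np.ndarray
    angular_speed: np.ndarray
    valid: np.ndarray
    frame_rate: float


@dataclass
class SegmentLabeling:
    """Per-frame locomotor state plus episode and event tables.

    ``states``: 1 = run, 0 = stop, per frame. Episode tables use half-open
    frame intervals [start, end). ``turn_labels``: 0 none, 1 smooth, 2 sharp.
    ``sharp_turn_events`` has one row per merged sharp-turn event at the
    frame of maximum windowed angular displacement.
    """

    states: np.ndarray
    run_episodes: pd.DataFrame
    stop_episodes: pd.DataFrame
    frame_rate: float
    turn_labels: np.ndarray | None = None
    sharp_turn_events: pd.DataFrame | None = None


@dataclass
class EpochSet:
    """Half-open [start, end) time intervals of the trial phases.

    ``during`` is entry-conditioned: it starts at odor-on + latency if the
    fly is inside the odor zone when the odor comes on, else at its first
    subsequent entry. ``during`` is None (with ``exclusion_reason``) for
    flies that never enter after odor onset.
    """

    before: tuple[float, float]
    during: tuple[float, float] | None
    after: tuple[float, float] | None
    exclusion_reason: str | None = None

    @property
    def excluded(self) -> bool:
        return self.during is None


STATE_STOP, STATE_RUN = 0, 1
TURN_NONE, TURN_SMOOTH, TURN_SHARP = 0, 1, 2


def smooth_track(traj: Trajectory, window: int = 10) -> Trajectory:
    """Centered moving-average smoothing of x and y (default 10 frames,
    0.33 s at 30 fps); edges use shrunken windows.

    An even window is centered exactly by giving the two end samples half
    weight (kernel length window+1), so linear motion passes through
    unchanged instead of acquiring a half-frame lag.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(traj) < window:
        raise SegmentationError(
            f"record of {len(traj)} frames is shorter than the {window}-frame window"
        )
    if window % 2 == 0:
        kernel = np.ones(window + 1)
        kernel[0] = kernel[-1] = 0.5
    else:
        kernel = np.ones(window)
    # normalized convolution: edges average over the shrunken window
    norm = np.convolve(np.ones(len(traj)), kernel, mode="same")
    xs = np.convolve(traj.x, kernel, mode="same") / norm
    ys = np.convolve(traj.y, kernel, mode="same") / norm
    return traj.with_positions(xs, ys)


def compute_kinematics(
    traj: Trajectory, min_speed_for_angular: float = 0.2
) -> KinematicSeries:
    """Speed, heading and signed angular speed from a (smoothed) trajectory.

    speed[i] = |p[i+1] - p[i]| * frame_rate (last frame repeats); heading[i]
    is the direction of that displacement, carried over frames slower than
    ``min_speed_for_angular`` (default 0.2 cm/s); angular_speed[i] is the
    wrapped heading change into frame i times the frame rate, NaN on frames
    below the floor.
    """
    n = len(traj)
    if n < 3:
        raise SegmentationError("need at least 3 frames for kinematics")
    fps = traj.frame_rate
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    speed = np.hypot(dx, dy) * fps
    speed = np.append(speed, speed[-1])
    valid = speed >= min_speed_for_angular

    raw_heading = np.arctan2(dy, dx)
    raw_heading = np.append(raw_heading, raw_heading[-1])
    heading = _fill_heading(raw_heading, valid)

    dh = np.diff(heading)
    dh = (dh + np.pi) % (2 * np.pi) - np.pi
    angular_speed = np.full(n, np.nan)
    angular_speed[1:] = dh * fps
    angular_speed[~valid] = np.nan
    angular_speed[0] = np.nan
    return KinematicSeries(
        speed=speed,
        heading=heading,
        angular_speed=angular_speed,
        valid=valid,
        frame_rate=fps,
    )


def _fill_heading(heading: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Forward-fill heading over invalid frames (backfill a leading gap)."""
    out = heading.copy()
    if valid.any():
        idx = np.where(valid, np.arange(len(valid)), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(valid)
        idx[idx < 0] = first
        out = heading[idx]
    return out


def schmidt_states(
    speed: np.ndarray, stop_threshold: float = 0.05, run_threshold: float = 0.1
) -> np.ndarray:
    """Hysteresis (Schmidt trigger) run/stop labeling of one or many speed
    traces (last axis = frames).

    Strictly below ``stop_threshold`` -> stop; strictly above
    ``run_threshold`` -> run; the dead band continues the previous state, and
    leading dead-band frames take the first decisive state (backfilled).
    """
    if stop_threshold >= run_threshold:
        raise ValueError("stop_threshold must be < run_threshold")
    speed = np.asarray(speed, dtype=float)
    decisive = np.full(speed.shape, np.nan)
    decisive[speed < stop_threshold] = STATE_STOP
    decisive[speed > run_threshold] = STATE_RUN
    flat = decisive.reshape(-1, speed.shape[-1])
    known = ~np.isnan(flat)
    if not known.any(axis=-1).all():
        raise SegmentationError(
            "all frames lie in the dead band; run/stop state undeterminable"
        )
    n = flat.shape[-1]
    # forward fill then backfill the leading gap
    idx = np.where(known, np.arange(n)[None, :], -1)
    idx = np.maximum.accumulate(idx, axis=-1)
    first = known.argmax(axis=-1)
    idx = np.where(idx < 0, first[:, None], idx)
    states = np.take_along_axis(flat, idx, axis=-1)
    return states.reshape(speed.shape).astype(np.uint8)


def _episodes(states: np.ndarray, fps: float, which: int) -> pd.DataFrame:
    """Maximal same-state intervals [start, end) with durations in s."""
    n = len(states)
    edges = np.flatnonzero(np.diff(states.astype(np.int8)) != 0) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [n]))
    keep = states[starts] == which
    df = pd.DataFrame(
        {
            "start": starts[keep],
            "end": ends[keep],
        }
    )
    df["duration_s"] = (df["end"] - df["start"]) / fps
    return df


def segment_runs_stops(
    speed: np.ndarray,
    stop_threshold: float = 0.05,
    run_threshold: float = 0.1,
    frame_rate: float = 30.0,
) -> SegmentLabeling:
    """Schmidt-trigger segmentation of a speed trace into run and stop
    episodes."""
    states = schmidt_states(np.atleast_1d(speed), stop_threshold, run_threshold)
    return SegmentLabeling(
        states=states,
        run_episodes=_episodes(states, frame_rate, STATE_RUN),
        stop_episodes=_episodes(states, frame_rate, STATE_STOP),
        frame_rate=frame_rate,
    )


def turn_statistic(
    angular_speed: np.ndarray, frame_rate: float, window: int = 5
) -> np.ndarray:
    """|net angular displacement| over the ``window`` frames ending at each
    frame. NaN (below-floor) frames contribute zero displacement, which —
    because angular speed is computed from carried headings — bridges slow
    gaps without losing net rotation. First window-1 frames are NaN."""
    disp = np.asarray(angular_speed, dtype=float) / frame_rate
    disp = np.nan_to_num(disp, nan=0.0)
    c = np.concatenate(([0.0], np.cumsum(disp)))
    n = len(disp)
    if window > n:
        raise SegmentationError("turn window longer than the record")
    s = np.full(n, np.nan)
    s[window - 1 :] = np.abs(c[window:] - c[: n - window + 1])
    return s


def classify_turns(
    angular_speed: np.ndarray,
    frame_rate: float,
    window: int = 5,
    smooth_threshold: float = 0.3,
    sharp_threshold: float = 1.3,
    states: np.ndarray | None = None,
    times: np.ndarray | None = None,
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label turning frames and merge sharp frames into events.

    Returns (per-frame labels, sharp-turn event table). A frame is turning
    when the windowed statistic S exceeds ``smooth_threshold`` and sharp when
    it exceeds ``sharp_threshold``; contiguous sharp frames form one event
    whose representative frame maximizes S. If run/stop ``states`` are given,
    only run frames carry turn labels.
    """
    s = turn_statistic(angular_speed, frame_rate, window)
    labels = np.zeros(len(s), dtype=np.uint8)
    with np.errstate(invalid="ignore"):
        labels[s > smooth_threshold] = TURN_SMOOTH
        labels[s > sharp_threshold] = TURN_SHARP
    if states is not None:
        labels[np.asarray(states) != STATE_RUN] = TURN_NONE

    sharp = labels == TURN_SHARP
    edges = np.flatnonzero(np.diff(sharp.astype(np.int8)) != 0) + 1
    bounds = np.concatenate(([0], edges, [len(sharp)]))
    segs = [
        [int(a), int(b)]
        for a, b in zip(bounds[:-1], bounds[1:])
        if sharp[a]
    ]
    # sharp segments separated by less than the window share rotation from
    # the same maneuver: merge them into one event
    merged: list[list[int]] = []
    for a, b in segs:
        if merged and a - merged[-1][1] < window:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    rows = []
    disp = np.nan_to_num(np.asarray(angular_speed, float) / frame_rate, nan=0.0)
    c = np.concatenate(([0.0], np.cumsum(disp)))
    for a, b in merged:
        seg = s[a:b]
        peak = a + int(np.nanargmax(seg))
        # signed net rotation over the peak window
        lo = max(0, peak - window + 1)
        magnitude = float(c[peak + 1] - c[lo])
        rows.append(
            {
                "frame": peak,
                "start": int(a),
                "end": int(b),
                "time": float(times[peak]) if times is not None else peak / frame_rate,
                "x": float(x[peak]) if x is not None else np.nan,
                "y": float(y[peak]) if y is not None else np.nan,
                "magnitude": magnitude,
            }
        )
    events = pd.DataFrame(
        rows, columns=["frame", "start", "end", "time", "x", "y", "magnitude"]
    )
    return labels, events


def segment(
    traj: Trajectory,
    kin: KinematicSeries | None = None,
    smoothing_window: int = 10,
    stop_threshold: float = 0.05,
    run_threshold: float = 0.1,
    min_speed_for_angular: float = 0.2,
    turn_window: int = 5,
    smooth_turn_threshold: float = 0.3,
    sharp_turn_threshold: float = 1.3,
    presmoothed: bool = False,
) -> tuple[Trajectory, KinematicSeries, SegmentLabeling]:
    """Convenience wrapper: smooth, compute kinematics, segment runs/stops
    and classify turns, in the published order with the published defaults."""
    smoothed = traj if presmoothed else smooth_track(traj, smoothing_window)
    if kin is None:
        kin = compute_kinematics(smoothed, min_speed_for_angular)
    labeling = segment_runs_stops(
        kin.speed, stop_threshold, run_threshold, traj.frame_rate
    )
    labels, events = classify_turns(
        kin.angular_speed,
        traj.frame_rate,
        turn_window,
        smooth_turn_threshold,
        sharp_turn_threshold,
        states=labeling.states,
        times=traj.times,
        x=smoothed.x,
        y=smoothed.y,
    )
    labeling.turn_labels = labels
    labeling.sharp_turn_events = events
    return smoothed, kin, labeling


def delineate_epochs(
    traj: Trajectory,
    odor_on: float = 180.0,
    odor_latency: float = 5.0,
    odor_duration: float = 180.0,
) -> EpochSet:
    """Before/during/after intervals with the entry-conditioned start of
    'during'."""
    t_end = float(traj.times[-1]) + 1.0 / traj.frame_rate
    if not 0 < odor_on < t_end:
        raise ValueError("odor_on must fall within the record")
    before = (0.0, odor_on)
    inside = traj.inside_zone()
    i_on = int(np.searchsorted(traj.times, odor_on))
    during_end = min(odor_on + odor_duration, t_end)
    if i_on < len(traj) and inside[i_on]:
        during_start = odor_on + odor_latency
    else:
        later = np.flatnonzero(inside[i_on:])
        if len(later) == 0:
            return EpochSet(
                before=before,
                during=None,
                after=(during_end, t_end) if t_end > during_end else None,
                exclusion_reason="fly never entered the odor zone after odor onset",
            )
        during_start = float(traj.times[i_on + later[0]])
    if during_start >= during_end:
        return EpochSet(
            before=before,
            during=None,
            after=(during_end, t_end) if t_end > during_end else None,
            exclusion_reason="fly entered the odor zone only after the odor period ended",
        )
    after = (during_end, t_end) if t_end > during_end else None
    return EpochSet(before=before, during=(during_start, during_end), after=after)


def _debounce(mask: np.ndarray, min_frames: int) -> np.ndarray:
    """Suppress boundary chatter: flip interior segments shorter than
    ``min_frames`` (short inside dwells first, then short outside gaps)."""
    if min_frames <= 1:
        return mask
    out = mask.copy()
    for target in (True, False):
        edges = np.flatnonzero(np.diff(out.astype(np.int8))) + 1
        bounds = np.concatenate(([0], edges, [len(out)]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            if out[a] == target and (b - a) < min_frames and a > 0 and b < len(out):
                out[a:b] = not target
    return out


def detect_transits(
    traj: Trajectory,
    boundary_radius: float | None = None,
    debounce: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Odor-zone visits (transits) and the outside intervals between them.

    A transit runs from the frame where the radial distance crosses to
    <= ``boundary_radius`` until the frame it crosses back. Returns
    (transits, outside_intervals) with half-open frame intervals, entry/exit
    times and dwell durations in s; the last interval of each kind is
    open-ended (``complete`` = False).
    """
    r_b = (
        traj.arena.odor_zone_radius if boundary_radius is None else boundary_radius
    )
    if r_b >= traj.arena.arena_radius:
        raise ValueError("boundary_radius must be smaller than the arena radius")
    inside = _debounce(traj.radius <= r_b, debounce)
    fps = traj.frame_rate

    def intervals(mask: np.ndarray) -> pd.DataFrame:
        edges = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
        bounds = np.concatenate(([0], edges, [len(mask)]))
        rows = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if mask[a]:
                rows.append(
                    {
                        "entry_frame": int(a),
                        "exit_frame": int(b),
                        "entry_time": a / fps,
                        "exit_time": b / fps,
                        "dwell_s": (b - a) / fps,
                        "complete": b < len(mask),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "entry_frame",
                "exit_frame",
                "entry_time",
                "exit_time",
                "dwell_s",
                "complete",
            ],
        )

    return intervals(inside), intervals(~inside)
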