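"""File formats: trajectory tables, per-frame label tables, feature tables.

The trajectory dialect is a TSV with header
``fly_id  frame  time_s  x_cm  y_cm  flagged``, 0-based frames,
arena-centered coordinates in cm, and empty fields for missing positions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import ArenaGeometry
from .trajectory import Trajectory

TRAJECTORY_COLUMNS = ["fly_id", "frame", "time_s", "x_cm", "y_cm", "flagged"]


class FormatError(ValueError):
    pass


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "fly_id": traj.fly_id,
            "frame": np.arange(len(traj)),
            "time_s": traj.times,
            "x_cm": traj.x,
            "y_cm": traj.y,
            "flagged": traj.flagged.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_trajectory(
    path: str | Path, arena: ArenaGeometry | None = None
) -> list[Trajectory]:
    """Read one or many flies from a trajectory TSV (grouped by fly_id)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - reported with filename
        raise FormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for fly_id, sub in df.groupby("fly_id", sort=False):
        sub = sub.sort_values("frame")
        times = sub["time_s"].to_numpy(float)
        if len(times) < 2:
            raise FormatError(f"{path}: fly {fly_id!r} has fewer than 2 frames")
        dt = np.diff(times)
        if np.any(dt <= 0):
            bad = int(sub["frame"].to_numpy()[1:][dt <= 0][0])
            raise FormatError(
                f"{path}: fly {fly_id!r}, frame {bad}, column time_s: "
                "times not strictly increasing"
            )
        frame_rate = 1.0 / float(np.median(dt))
        if abs(frame_rate - round(frame_rate)) < 0.05:
            frame_rate = float(round(frame_rate))
        # regenerate exact uniform times: written tables round time_s
        frames = sub["frame"].to_numpy(float)
        times = times[0] + (frames - frames[0]) / frame_rate
        out.append(
            Trajectory(
                fly_id=str(fly_id),
                times=times,
                x=sub["x_cm"].to_numpy(float),
                y=sub["y_cm"].to_numpy(float),
                frame_rate=frame_rate,
                arena=arena or ArenaGeometry(),
                flagged=sub["flagged"].to_numpy(float) > 0,
            )
        )
    if not out:
        raise FormatError(f"{path}: no trajectories found")
    return out


def write_labels(
    path: str | Path,
    states: np.ndarray,
    turn_labels: np.ndarray | None = None,
    context: np.ndarray | None = None,
) -> None:
    """Per-frame label TSV parallel to a trajectory table."""
    data = {"frame": np.arange(len(states)), "state": np.asarray(states, int)}
    if turn_labels is not None:
        data["turn"] = np.asarray(turn_labels, int)
    if context is not None:
        data["context"] = np.asarray(context, int)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "state" not in df.columns:
        raise FormatError(f"{path}: missing 'state' column")
    return df


def write_profile(profile, path: str | Path) -> None:
    """Long-format profile TSV: bin_start, bin_end, value, n."""
    pd.DataFrame(
        {
            "bin_start": profile.bin_edges[:-1],
            "bin_end": profile.bin_edges[1:],
            "value": profile.values,
            "n": profile.n,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
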