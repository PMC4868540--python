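"""Single-fly centroid tracking from grayscale frame stacks.

The fly is the only bright object on a dark background: we subtract the
pixel-wise mean frame, threshold (Otsu by default), and take the
intensity-weighted centroid of the largest connected bright component.
Frames whose implied instantaneous speed exceeds a jump limit are flagged as
mis-assignments and repaired by linear interpolation between neighboring
accepted frames, mirroring how such tracking errors are found and corrected
in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .config import ArenaGeometry
from .trajectory import Trajectory


@dataclass
class FrameStack:
    """An ordered stack of same-shape grayscale frames."""

    frames: np.ndarray  # (n, rows, cols)
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-world calibration: mm per px plus the arena's pixel center
    and radius."""

    pixel_scale: float
    center_row: float
    center_col: float
    arena_radius_px: float

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")


@dataclass
class RawTrack:
    """Per-frame pixel centroids with validity flags.

    ``missing`` marks frames with no object above threshold; ``flagged``
    marks frames whose position violated the jump limit and was repaired by
    interpolation. ``flag_reasons`` records why each flagged/missing frame
    was touched.
    """

    rows: np.ndarray
    cols: np.ndarray
    missing: np.ndarray
    flagged: np.ndarray
    pixel_scale: float
    frame_rate: float
    flag_reasons: dict[int, str]

    def __len__(self) -> int:
        return len(self.rows)


class TrackingError(RuntimeError):
    pass


def calibrate_pixels(
    arena_diameter_px: float,
    arena_diameter_cm: float,
    center: tuple[float, float] | None = None,
) -> Calibration:
    """Calibration from the measured arena diameter.

    pixel_scale = 10 * diameter_cm / diameter_px (mm per px); e.g. a 6.4 cm
    arena spanning 640 px gives 0.1 mm/px.
    """
    if arena_diameter_px <= 0 or arena_diameter_cm <= 0:
        raise ValueError("arena diameters must be positive")
    row, col = center if center is not None else (0.0, 0.0)
    return Calibration(
        pixel_scale=10.0 * arena_diameter_cm / arena_diameter_px,
        center_row=row,
        center_col=col,
        arena_radius_px=arena_diameter_px / 2.0,
    )


def estimate_background(stack: FrameStack) -> np.ndarray:
    """Pixel-wise mean frame. With the fly moving, each pixel's mean is
    dominated by the static background."""
    if len(stack) < 2:
        raise ValueError("background estimation needs at least 2 frames")
    return stack.frames.mean(axis=0)


def _frame_centroid(
    sub: np.ndarray, threshold: float | None
) -> tuple[float, float] | None:
    """Intensity-weighted centroid of the largest bright component of one
    background-subtracted frame, or None if nothing credible is bright."""
    # guard against pure-noise frames: the brightest pixel must stand out
    # from the robust noise scale before Otsu is even attempted
    sigma = 1.4826 * np.median(np.abs(sub - np.median(sub))) + 1e-12
    if sub.max() < 6.0 * sigma:
        return None
    thr = threshold_otsu(sub) if threshold is None else threshold
    mask = sub > thr
    if not mask.any():
        return None
    labels = cc_label(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = counts.argmax()
    rr, cc = np.nonzero(labels == biggest)
    w = sub[rr, cc]
    w = np.clip(w, 0.0, None)
    tot = w.sum()
    if tot <= 0:
        return None
    return float((rr * w).sum() / tot), float((cc * w).sum() / tot)


def track_centroid(
    stack: FrameStack,
    background: np.ndarray,
    calib: Calibration,
    jump_limit: float = 3.0,
    threshold: float | None = None,
    max_missing_fraction: float = 0.2,
) -> RawTrack:
    """Track the fly across a stack.

    ``jump_limit`` is in cm/s: frames whose implied instantaneous speed from
    the last accepted position exceeds it are flagged as misassignments and
    their positions replaced by linear interpolation between neighboring
    accepted frames. ``threshold`` overrides Otsu with a fixed value.
    """
    if background.shape != stack.frames.shape[1:]:
        raise ValueError("background shape does not match frames")
    n = len(stack)
    rows = np.full(n, np.nan)
    cols = np.full(n, np.nan)
    missing = np.zeros(n, dtype=bool)
    reasons: dict[int, str] = {}
    for i in range(n):
        sub = stack.frames[i] - background
        cent = _frame_centroid(sub, threshold)
        if cent is None:
            missing[i] = True
            reasons[i] = "no bright object above threshold"
        else:
            rows[i], cols[i] = cent
    if missing.mean() > max_missing_fraction:
        raise TrackingError(
            f"{missing.sum()} of {n} frames ({missing.mean():.0%}) have no "
            "trackable object"
        )

    # jump-limit screening against the last accepted position
    limit_px_per_s = jump_limit * 10.0 / calib.pixel_scale
    flagged = np.zeros(n, dtype=bool)
    last_good = None
    for i in range(n):
        if missing[i]:
            continue
        if last_good is not None:
            gap = (i - last_good) / stack.frame_rate
            dist = np.hypot(rows[i] - rows[last_good], cols[i] - cols[last_good])
            if dist / gap > limit_px_per_s:
                flagged[i] = True
                reasons[i] = (
                    f"implied speed {dist / gap * calib.pixel_scale / 10.0:.2f} cm/s "
                    f"exceeds jump limit {jump_limit:g} cm/s"
                )
                continue
        last_good = i

    # repair flagged (and missing) positions by linear interpolation
    # between accepted anchors; leading/trailing gaps keep the nearest anchor
    good = ~(flagged | missing)
    if good.sum() == 0:
        raise TrackingError("no frames survived the jump-limit screen")
    idx = np.arange(n)
    rows_fixed = rows.copy()
    cols_fixed = cols.copy()
    bad = ~good
    rows_fixed[bad] = np.interp(idx[bad], idx[good], rows[good])
    cols_fixed[bad] = np.interp(idx[bad], idx[good], cols[good])

    return RawTrack(
        rows=rows_fixed,
        cols=cols_fixed,
        missing=missing,
        flagged=flagged,
        pixel_scale=calib.pixel_scale,
        frame_rate=stack.frame_rate,
        flag_reasons=reasons,
    )


def to_trajectory(
    track: RawTrack,
    calib: Calibration,
    arena: ArenaGeometry | None = None,
    fly_id: str = "fly",
) -> Trajectory:
    """Convert a pixel track to an arena-centered trajectory in cm (y grows
    upward, image rows grow downward)."""
    arena = arena or ArenaGeometry()
    x = (track.cols - calib.center_col) * calib.pixel_scale / 10.0
    y = (calib.center_row - track.rows) * calib.pixel_scale / 10.0
    times = np.arange(len(track)) / track.frame_rate
    return Trajectory(
        fly_id=fly_id,
        times=times,
        x=x,
        y=y,
        frame_rate=track.frame_rate,
        arena=arena,
        flagged=track.flagged | track.missing,
    )
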