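"""The in-memory trajectory container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import ArenaGeometry


@dataclass
class Trajectory:
    """Time-stamped arena-centered positions of one fly.

    Coordinates are Cartesian cm with the arena center at the origin; time is
    0-based seconds sampled uniformly at ``frame_rate``. ``flagged`` marks
    frames whose position was repaired or suspect upstream (tracking).
    """

    fly_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.times)
        if len(self.x) != n or len(self.y) != n:
            raise ValueError("times, x, y must have equal length")
        if n >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.frame_rate, rtol=1e-3, atol=1e-6):
                raise ValueError("times must be uniformly spaced at 1/frame_rate")
        if self.flagged is None:
            self.flagged = np.zeros(n, dtype=bool)
        else:
            self.flagged = np.asarray(self.flagged, dtype=bool)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def radius(self) -> np.ndarray:
        """Radial distance from the arena center, cm."""
        return np.hypot(self.x, self.y)

    def inside_zone(self, boundary: float | None = None) -> np.ndarray:
        """Boolean mask of frames at or inside the given radial boundary
        (default: the arena's nominal odor-zone radius)."""
        r = self.arena.odor_zone_radius if boundary is None else boundary
        return self.radius <= r

    def with_positions(self, x: np.ndarray, y: np.ndarray) -> "Trajectory":
        return replace(self, x=np.asarray(x, float), y=np.asarray(y, float))
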