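"""Configuration objects for the arena, the synthetic walker, video rendering
and the full analysis pipeline.

All defaults are the constants of the assay this package quantifies: a 6.4 cm
diameter circular arena filmed at 30 frames/s, with a central odor zone of
radius 1.2 cm (conservative centroid boundary 1.9 cm), odor turned on at
3 min with a 5 s delivery latency, a 10-frame track-smoothing window,
Schmidt-trigger run/stop thresholds of 0.05 / 0.1 cm/s, a 5-frame turn window
with 0.3 / 1.3 rad smooth/sharp thresholds, and a 2 mm/s floor below which
angular speed is disregarded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Geometry of the circular two-zone arena, in cm.

    ``odor_zone_radius`` is the nominal physical odor boundary (the inner
    rim); ``odor_boundary_radius`` is the boundary used for the sharp-turn
    ring, which may be set to the conservative 1.9 cm estimate for undiluted
    attractant; ``turn_ring_halfwidth`` is the half-width of the ring around
    that boundary within which sharp turns count as "at the border".
    """

    arena_radius: float = 3.2
    odor_zone_radius: float = 1.2
    odor_boundary_radius: float = 1.2
    turn_ring_halfwidth: float = 0.2

    def __post_init__(self) -> None:
        if self.arena_radius <= 0:
            raise ConfigurationError("arena_radius must be positive")
        if not 0 < self.odor_zone_radius < self.arena_radius:
            raise ConfigurationError(
                "odor_zone_radius must lie in (0, arena_radius)"
            )
        if not 0 < self.odor_boundary_radius < self.arena_radius:
            raise ConfigurationError(
                "odor_boundary_radius must lie in (0, arena_radius)"
            )


@dataclass(frozen=True)
class ContextParams:
    """Locomotor parameters of the walker in one context.

    A context is one cell of {before, during} x {inside, outside the odor
    zone}. Durations are medians of log-normal laws (s), speeds in cm/s,
    heading diffusion in rad^2/s, sharp-turn rate in events/s during runs.
    ``wall_attraction`` in [0, 1] is the probability that a wall contact
    aligns the heading tangentially instead of reflecting it.
    ``boundary_turn_bias`` in [0, 1] is the probability, drawn once per entry
    into the 2 mm ring around the odor boundary while the odor is on, of an
    inward-directed sharp turn.
    """

    median_run_duration: float = 4.81
    median_stop_duration: float = 0.67
    median_run_speed: float = 0.57
    heading_diffusion: float = 0.3
    sharp_turn_rate: float = 0.1
    sharp_turn_angle: float = 2.6
    wall_attraction: float = 0.8
    boundary_turn_bias: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "median_run_duration",
            "median_stop_duration",
            "median_run_speed",
            "sharp_turn_angle",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("heading_diffusion", "sharp_turn_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("wall_attraction", "boundary_turn_bias"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")


def _default_before_inside() -> ContextParams:
    return ContextParams()


def _default_before_outside() -> ContextParams:
    return ContextParams()


def _default_during_inside() -> ContextParams:
    # Strong-attractant response: short slow runs, short stops, frequent
    # sharp turns, inward bias at the border.
    return ContextParams(
        median_run_duration=1.0,
        median_stop_duration=0.3,
        median_run_speed=0.18,
        sharp_turn_rate=0.25,
        boundary_turn_bias=0.35,
    )


def _default_during_outside() -> ContextParams:
    return ContextParams(
        median_run_duration=2.0,
        median_stop_duration=0.3,
        median_run_speed=0.57,
        sharp_turn_rate=0.2,
        wall_attraction=0.3,
        boundary_turn_bias=0.35,
    )


@dataclass(frozen=True)
class WalkerConfig:
    """Full configuration of the semi-Markov run/stop walker.

    The trial layout mirrors the assay: ``duration_before`` seconds with no
    odor followed by ``duration_during`` seconds with odor on; the odor-on
    time is ``duration_before``. Episode durations follow log-normal laws
    parameterized by their median and a log-scale shape ``sigma_log``
    (default 0.8, giving the heavy right tails seen in real runs/stops).
    """

    frame_rate: float = 30.0
    duration_before: float = 180.0
    duration_during: float = 180.0
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    before_inside: ContextParams = field(default_factory=_default_before_inside)
    before_outside: ContextParams = field(default_factory=_default_before_outside)
    during_inside: ContextParams = field(default_factory=_default_during_inside)
    during_outside: ContextParams = field(default_factory=_default_during_outside)
    sigma_log: float = 0.8
    speed_ramp_frames: int = 10
    stop_speed_ceiling: float = 0.05

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        for name in ("duration_before", "duration_during"):
            dur = getattr(self, name)
            if dur <= 0:
                raise ConfigurationError(f"{name} must be positive")
            if dur * self.frame_rate < 2:
                raise ConfigurationError(f"{name} is shorter than 2 frames")
        if self.sigma_log < 0:
            raise ConfigurationError("sigma_log must be non-negative")

    def context(self, during: bool, inside: bool) -> ContextParams:
        if during:
            return self.during_inside if inside else self.during_outside
        return self.before_inside if inside else self.before_outside

    @property
    def odor_on(self) -> float:
        return self.duration_before

    @property
    def n_frames(self) -> int:
        return int(round((self.duration_before + self.duration_during) * self.frame_rate))


def null_walker_config(**overrides: Any) -> WalkerConfig:
    """A walker whose during-period parameters equal the before-period ones
    (solvent-control conditions: the odor changes nothing)."""
    base = ContextParams()
    return WalkerConfig(
        during_inside=base, during_outside=base, **overrides
    )


@dataclass(frozen=True)
class VideoConfig:
    """Rendering parameters for synthetic arena videos.

    ``pixel_scale`` is mm per pixel. The fly is a Gaussian blob of e-folding
    radius ``blob_radius`` px on a static textured background plus i.i.d.
    Gaussian noise.
    """

    image_size: int = 72
    pixel_scale: float = 1.0
    blob_radius: float = 1.5
    blob_intensity: float = 1.0
    background_intensity: float = 0.1
    noise_sd: float = 0.02
    texture_amplitude: float = 0.02
    texture_seed: int = 1234

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ConfigurationError("image_size must be at least 8 px")
        if self.pixel_scale <= 0:
            raise ConfigurationError("pixel_scale must be positive")
        if self.blob_intensity <= self.background_intensity + 3 * self.noise_sd:
            raise ConfigurationError(
                "blob_intensity must exceed background_intensity + 3 * noise_sd"
            )


@dataclass(frozen=True)
class PipelineConfig:
    """Aggregated settings for the end-to-end analysis pipeline.

    Every default is the assay's printed constant; overrides are recorded in
    the run manifest.
    """

    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    odor_on: float = 180.0
    odor_latency: float = 5.0
    smoothing_window: int = 10
    stop_threshold: float = 0.05
    run_threshold: float = 0.1
    min_speed_for_angular: float = 0.2
    turn_window: int = 5
    smooth_turn_threshold: float = 0.3
    sharp_turn_threshold: float = 1.3
    transit_debounce: int = 2
    jump_limit: float = 3.0  # cm/s; tracking error flag threshold
    alpha: float = 0.05
    n_permutations: int = 50_000
    ridge: float = 0.0
    standardize_pca: bool = True
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return _as_plain_dict(self)


def _as_plain_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _as_plain_dict(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    return obj


_NESTED_FIELDS = {
    "arena": ArenaGeometry,
    "before_inside": ContextParams,
    "before_outside": ContextParams,
    "during_inside": ContextParams,
    "during_outside": ContextParams,
}


def _from_dict(cls: type, data: dict[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    for key, value in data.items():
        sub = _NESTED_FIELDS.get(key)
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _from_dict(sub, value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def save_config(config: Any, path: str) -> None:
    """Serialize any of the config dataclasses to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"kind": type(config).__name__, "config": _as_plain_dict(config)},
            fh,
            sort_keys=False,
        )


_KINDS = {
    "ArenaGeometry": ArenaGeometry,
    "ContextParams": ContextParams,
    "WalkerConfig": WalkerConfig,
    "VideoConfig": VideoConfig,
    "PipelineConfig": PipelineConfig,
}


def load_config(path: str, kind: type | None = None) -> Any:
    """Load a config previously written by :func:`save_config`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "config" not in payload:
        raise ConfigurationError(f"{path}: not a flywalk config file")
    cls = kind or _KINDS.get(payload.get("kind", ""))
    if cls is None:
        raise ConfigurationError(f"{path}: unknown config kind {payload.get('kind')!r}")
    return _from_dict(cls, payload["config"])
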