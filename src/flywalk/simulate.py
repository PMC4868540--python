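"""Semi-Markov run/stop walker and synthetic video rendering.

The walker alternates run and stop episodes whose durations are drawn from
log-normal laws parameterized by their configured medians (heavy right tails,
as real runs and stops show). During runs the heading diffuses by Gaussian
increments and is punctuated by discrete sharp-turn events; speed follows the
episode's plateau through short linear accelerate/decelerate ramps, so
episode boundaries look like real starts and stops rather than step
functions. Position reflects off the arena wall, with a configurable
probability of aligning tangentially instead (edge dwelling). Parameters
switch instantaneously with context: {before, during odor} x {inside,
outside the odor zone}.

Every simulation also returns per-frame ground-truth labels so downstream
segmentation and feature extraction can be tested without any recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, VideoConfig, WalkerConfig
from .trajectory import Trajectory

# context codes in GroundTruth.context
CTX_BEFORE_OUT, CTX_BEFORE_IN, CTX_DURING_OUT, CTX_DURING_IN = 0, 1, 2, 3

STATE_STOP, STATE_RUN = 0, 1
TURN_NONE, TURN_SMOOTH, TURN_SHARP = 0, 1, 2


@dataclass
class GroundTruth:
    """Per-frame truth emitted by the simulator.

    ``state`` is run/stop, ``turn_label`` marks sharp-turn frames (and
    post-hoc smooth-turn frames, see :func:`_label_smooth_turns`),
    ``context`` the {before,during} x {in,out} cell, ``speed``/``heading``
    the true kinematics used to advance the walker.
    """

    state: np.ndarray
    turn_label: np.ndarray
    context: np.ndarray
    speed: np.ndarray
    heading: np.ndarray
    sharp_turn_frames: np.ndarray
    sharp_turn_times: np.ndarray
    sharp_turn_x: np.ndarray
    sharp_turn_y: np.ndarray
    sharp_turn_angles: np.ndarray
    wall_frames: np.ndarray = None  # frames with wall-contact heading changes

    def __len__(self) -> int:
        return len(self.state)


def _sample_duration_frames(
    rng: np.random.Generator, median: float, sigma: float, fps: float, n_max: int
) -> int:
    """Log-normal episode duration, in frames, clipped to [2, n_max]."""
    if math.isinf(median):
        return n_max
    dur = rng.lognormal(mean=math.log(median), sigma=sigma)
    return int(min(max(2, round(dur * fps)), n_max))


def _wrap(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def simulate_fly(
    config: WalkerConfig, seed: int, fly_id: str = "fly"
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one fly for the configured before + during durations.

    All randomness derives from ``seed``; identical (config, seed) pairs give
    bit-identical output.
    """
    if not isinstance(config, WalkerConfig):
        raise ConfigurationError("config must be a WalkerConfig")
    rng = np.random.default_rng(seed)
    fps = config.frame_rate
    dt = 1.0 / fps
    n = config.n_frames
    odor_on = config.odor_on
    arena = config.arena
    r_arena = arena.arena_radius
    r_zone = arena.odor_zone_radius
    r_ring = arena.odor_boundary_radius
    ring_hw = arena.turn_ring_halfwidth
    sigma = config.sigma_log
    ramp = max(1, config.speed_ramp_frames)

    x = np.empty(n)
    y = np.empty(n)
    state_arr = np.empty(n, dtype=np.uint8)
    turn_arr = np.zeros(n, dtype=np.uint8)
    ctx_arr = np.empty(n, dtype=np.uint8)
    speed_arr = np.zeros(n)
    heading_arr = np.empty(n)

    noise = rng.standard_normal(n)
    u_turn = rng.random(n)
    u_sign = rng.random(n)
    u_wall = rng.random(n)
    u_bias = rng.random(n)

    # start anywhere in the arena (slightly off the wall), random heading
    r0 = 0.9 * r_arena * math.sqrt(rng.random())
    th0 = rng.random() * 2 * math.pi
    px, py = r0 * math.cos(th0), r0 * math.sin(th0)
    heading = rng.random() * 2 * math.pi - math.pi

    state = STATE_RUN
    frames_left = 0
    ep_len = 0
    v_plateau = 0.0
    cur_speed = 0.0
    block = None
    in_ring_prev = False
    sharp_frames: list[int] = []
    sharp_angles: list[float] = []
    wall_frames: list[int] = []

    for i in range(n):
        t = i * dt
        r = math.hypot(px, py)
        during = t >= odor_on
        inside = r <= r_zone
        ctx_arr[i] = (2 if during else 0) + (1 if inside else 0)
        new_block = config.context(during, inside)

        if block is None:
            block = new_block
            state = STATE_RUN if rng.random() < 0.5 else STATE_STOP
            median = (
                block.median_run_duration
                if state == STATE_RUN
                else block.median_stop_duration
            )
            frames_left = _sample_duration_frames(rng, median, sigma, fps, n)
            ep_len = frames_left
            v_plateau = rng.lognormal(math.log(block.median_run_speed), 0.3)
        elif new_block != block:  # value comparison: identical parameter
            # blocks across a boundary are one behavioral context
            # context switch: resample the remaining episode from the new
            # block (only when the parameter block actually differs)
            block = new_block
            median = (
                block.median_run_duration
                if state == STATE_RUN
                else block.median_stop_duration
            )
            frames_left = _sample_duration_frames(rng, median, sigma, fps, n)
            ep_len = frames_left
            if state == STATE_RUN:
                v_plateau = rng.lognormal(math.log(block.median_run_speed), 0.3)

        if frames_left <= 0:
            # next episode, alternating state
            state = STATE_RUN if state == STATE_STOP else STATE_STOP
            median = (
                block.median_run_duration
                if state == STATE_RUN
                else block.median_stop_duration
            )
            frames_left = _sample_duration_frames(rng, median, sigma, fps, n)
            ep_len = frames_left
            if state == STATE_RUN:
                v_plateau = rng.lognormal(math.log(block.median_run_speed), 0.3)
                cur_speed = 0.0
            else:
                cur_speed = 0.0

        state_arr[i] = state
        x[i] = px
        y[i] = py

        if state == STATE_RUN:
            r_eff = max(1, min(ramp, ep_len // 3)) if ep_len >= 3 else 1
            j = ep_len - frames_left  # 0-based index within episode
            target = v_plateau * min(1.0, (j + 1) / r_eff, frames_left / r_eff)
            step_v = v_plateau / r_eff
            cur_speed += min(max(target - cur_speed, -step_v), step_v)

            # sharp turns: spontaneous Poisson events, plus an inward-biased
            # event on entry into the ring around the odor boundary. Sharp
            # turns are discrete reorientations of steady walking, so they
            # fire only in the plateau phase of a run (not in the
            # accelerate/decelerate tails, where the fly is effectively
            # starting or ending a stop).
            at_plateau = (j + 1) > r_eff and frames_left > r_eff
            in_ring = during and abs(r - r_ring) <= ring_hw
            forced_inward = (
                at_plateau
                and in_ring
                and not in_ring_prev
                and u_bias[i] < block.boundary_turn_bias
            )
            in_ring_prev = in_ring
            if forced_inward or (
                at_plateau and u_turn[i] < block.sharp_turn_rate * dt
            ):
                angle = block.sharp_turn_angle
                if forced_inward:
                    inward = math.atan2(-py, -px)
                    plus = abs(_wrap(heading + angle - inward))
                    minus = abs(_wrap(heading - angle - inward))
                    jump = angle if plus <= minus else -angle
                else:
                    jump = angle if u_sign[i] < 0.5 else -angle
                heading = _wrap(heading + jump)
                turn_arr[i] = TURN_SHARP
                sharp_frames.append(i)
                sharp_angles.append(jump)

            # thigmotaxis: wall_attraction also acts as wall-following
            # persistence, damping heading diffusion in a 1 mm boundary layer
            diffusion = block.heading_diffusion
            if r > r_arena - 0.1:
                diffusion *= 1.0 - block.wall_attraction
            heading = _wrap(heading + noise[i] * math.sqrt(diffusion * dt))

            step = cur_speed * dt
            nx, ny = px + step * math.cos(heading), py + step * math.sin(heading)
            if math.hypot(nx, ny) > r_arena:
                wall_frames.append(i)
                phi = math.atan2(py, px)  # radial direction at contact
                if u_wall[i] < block.wall_attraction:
                    # align with the tangent direction closest to the heading
                    t1 = _wrap(phi + math.pi / 2)
                    t2 = _wrap(phi - math.pi / 2)
                    heading = t1 if abs(_wrap(heading - t1)) <= abs(_wrap(heading - t2)) else t2
                else:
                    # specular reflection about the tangent
                    heading = _wrap(2 * phi + math.pi - heading)
                nx, ny = px + step * math.cos(heading), py + step * math.sin(heading)
                rn = math.hypot(nx, ny)
                if rn > r_arena:
                    nx, ny = nx * (r_arena - 1e-9) / rn, ny * (r_arena - 1e-9) / rn
            px, py = nx, ny
            speed_arr[i] = cur_speed
        else:
            cur_speed = 0.0
            in_ring_prev = during and abs(r - r_ring) <= ring_hw

        heading_arr[i] = heading
        frames_left -= 1

    times = np.arange(n) / fps
    traj = Trajectory(
        fly_id=fly_id, times=times, x=x, y=y, frame_rate=fps, arena=arena
    )
    sharp_frames_a = np.asarray(sharp_frames, dtype=int)
    truth = GroundTruth(
        state=state_arr,
        turn_label=turn_arr,
        context=ctx_arr,
        speed=speed_arr,
        heading=heading_arr,
        sharp_turn_frames=sharp_frames_a,
        sharp_turn_times=times[sharp_frames_a] if len(sharp_frames_a) else np.empty(0),
        sharp_turn_x=x[sharp_frames_a] if len(sharp_frames_a) else np.empty(0),
        sharp_turn_y=y[sharp_frames_a] if len(sharp_frames_a) else np.empty(0),
        sharp_turn_angles=np.asarray(sharp_angles),
        wall_frames=np.asarray(wall_frames, dtype=int),
    )
    _label_smooth_turns(truth, config)
    return traj, truth


def _label_smooth_turns(truth: GroundTruth, config: WalkerConfig) -> None:
    """Mark run frames whose true 5-frame net heading change exceeds 0.3 rad
    (and which are not sharp) as smooth-turn frames."""
    h = np.unwrap(truth.heading)
    n = len(h)
    if n < 6:
        return
    s = np.abs(h[5:] - h[:-5])  # net rotation over the 5 steps ending at i
    frames = np.arange(5, n)
    run = truth.state[frames] == STATE_RUN
    smooth = (s > 0.3) & run & (truth.turn_label[frames] == TURN_NONE)
    truth.turn_label[frames[smooth]] = TURN_SMOOTH


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Per-fly seeds derived reproducibly from a master seed (all < 2^31)."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n, dtype=np.uint64) % (2**31)


def simulate_cohort(
    config: WalkerConfig, n_flies: int, seed: int, id_prefix: str = "fly"
) -> list[tuple[Trajectory, GroundTruth]]:
    """``n_flies`` independent walkers with per-fly seeds derived from the
    master seed (reproducible; fly k always gets the same derived seed)."""
    if n_flies < 1:
        raise ConfigurationError("n_flies must be >= 1")
    seeds = derive_seeds(seed, n_flies)
    return [
        simulate_fly(config, int(s), fly_id=f"{id_prefix}{k:03d}")
        for k, s in enumerate(seeds)
    ]


def render_video(traj: Trajectory, vconf: VideoConfig, seed: int):
    """Render a trajectory as a synthetic grayscale frame stack.

    The fly is a Gaussian blob at the mapped pixel position over a static
    textured background plus i.i.d. Gaussian noise. Raises if the blob would
    leave the image, naming the offending frame.
    """
    from .tracking import FrameStack  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    size = vconf.image_size
    c = (size - 1) / 2.0
    # cm -> px: 10 mm/cm over pixel_scale mm/px; image rows grow downward
    cols = c + traj.x * 10.0 / vconf.pixel_scale
    rows = c - traj.y * 10.0 / vconf.pixel_scale
    margin = vconf.blob_radius
    bad = np.nonzero(
        (cols < margin) | (cols > size - 1 - margin)
        | (rows < margin) | (rows > size - 1 - margin)
    )[0]
    if len(bad):
        raise ValueError(
            f"frame {int(bad[0])}: blob at ({rows[bad[0]]:.1f}, {cols[bad[0]]:.1f}) px "
            f"would leave the {size}x{size} image"
        )

    texture_rng = np.random.default_rng(vconf.texture_seed)
    background = np.clip(
        vconf.background_intensity
        + vconf.texture_amplitude * texture_rng.standard_normal((size, size)),
        0.0,
        None,
    )
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    frames = np.empty((len(traj), size, size), dtype=np.float32)
    two_s2 = 2.0 * vconf.blob_radius**2
    for i in range(len(traj)):
        blob = vconf.blob_intensity * np.exp(
            -((rr - rows[i]) ** 2 + (cc - cols[i]) ** 2) / two_s2
        )
        frame = background + blob
        if vconf.noise_sd > 0:
            frame = frame + vconf.noise_sd * rng.standard_normal((size, size))
        frames[i] = frame
    return FrameStack(frames=frames, frame_rate=traj.frame_rate)


def render_background_video(
    n_frames: int, vconf: VideoConfig, seed: int, frame_rate: float = 30.0
):
    """A fly-free stack (background + noise only), for tracker negative
    controls."""
    from .tracking import FrameStack

    rng = np.random.default_rng(seed)
    size = vconf.image_size
    texture_rng = np.random.default_rng(vconf.texture_seed)
    background = np.clip(
        vconf.background_intensity
        + vconf.texture_amplitude * texture_rng.standard_normal((size, size)),
        0.0,
        None,
    )
    frames = (
        background[None, :, :]
        + vconf.noise_sd * rng.standard_normal((n_frames, size, size))
    ).astype(np.float32)
    return FrameStack(frames=frames, frame_rate=frame_rate)
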