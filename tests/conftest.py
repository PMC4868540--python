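import numpy as np
import pytest

import flywalk as fw


@pytest.fixture(scope="session")
def null_config():
    return fw.null_walker_config()


@pytest.fixture(scope="session")
def acv_config():
    return fw.WalkerConfig()


@pytest.fixture(scope="session")
def short_null_config():
    """A 60 s + 60 s null walker for cheap end-to-end tests."""
    return fw.null_walker_config(duration_before=60.0, duration_during=60.0)


def straight_trajectory(
    speed=0.5, n=300, frame_rate=30.0, start=(-2.0, 0.0), heading=0.0, **kw
):
    """A constant-velocity straight path (no smoothing artifacts inside)."""
    t = np.arange(n) / frame_rate
    x = start[0] + speed * t * np.cos(heading)
    y = start[1] + speed * t * np.sin(heading)
    return fw.Trajectory(
        fly_id="straight", times=t, x=x, y=y, frame_rate=frame_rate, **kw
    )


def score_turn_recovery(cfg, seeds, tol=8, wall_exclusion=12, clump=10):
    """Event-level sharp-turn recall and precision on simulated flies.

    Detections lag the maneuver by up to window−1 frames plus smoothing
    spread, hence the matching tolerance. Events within ``wall_exclusion``
    frames of a wall contact are excluded from scoring (wall reflections are
    genuine sharp path turns without a ground-truth event), and true events
    closer than ``clump`` frames are scored as one maneuver (a net-rotation
    window statistic cannot resolve or even see canceling back-to-back
    jumps).
    """
    rec_hit = rec_tot = prec_hit = prec_tot = 0
    for seed in seeds:
        traj, truth = fw.simulate_fly(cfg, seed)
        _sm, _kin, seg = fw.segment(traj)
        det = np.sort(seg.sharp_turn_events["frame"].to_numpy())
        true = np.sort(truth.sharp_turn_frames)
        wall = truth.wall_frames

        def dwall(f):
            return np.min(np.abs(wall - f)) if len(wall) else np.inf

        true_s = np.array([f for f in true if dwall(f) > wall_exclusion])
        det_s = np.array([f for f in det if dwall(f) > wall_exclusion])
        clumps = []
        for f in true_s:
            if clumps and f - clumps[-1][-1] <= clump:
                clumps[-1].append(f)
            else:
                clumps.append([f])
        rec_hit += sum(
            1
            for cl in clumps
            if len(det_s) and min(np.min(np.abs(det_s - f)) for f in cl) <= tol
        )
        rec_tot += len(clumps)
        prec_hit += sum(
            1 for f in det_s if len(true) and np.min(np.abs(true - f)) <= tol
        )
        prec_tot += len(det_s)
    return rec_hit / rec_tot, prec_hit / prec_tot


def schmidt_oracle(speeds, stop_threshold=0.05, run_threshold=0.1):
    """Brute-force two-threshold state machine, written as the plainest
    possible per-frame loop (independent of the vectorized implementation)."""
    states = []
    current = None
    for v in speeds:
        if v < stop_threshold:
            current = 0
        elif v > run_threshold:
            current = 1
        # else: keep previous state (may still be None)
        states.append(current)
    # backfill leading undecided frames with the first decisive state
    first = next((s for s in states if s is not None), None)
    if first is None:
        raise ValueError("all frames in dead band")
    out = []
    for s in states:
        if s is None:
            out.append(first)
        else:
            first = s  # after the first decisive frame this equals s
            out.append(s)
    return out
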