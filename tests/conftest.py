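import numpy as np
import pytest

from gesturekin import (
    CANONICAL_JOINTS,
    FeatureConfig,
    SkeletonSequence,
    extract_features,
    generate_dataset,
)


@pytest.fixture(scope="session")
def battery():
    """The standard noise-free 20-act ground-truthed battery."""
    seq, windows, truth_df, truths = generate_dataset(n_acts=20, seed=0, jitter_sd=0.0)
    return seq, windows, truth_df, truths


@pytest.fixture(scope="session")
def battery_features(battery):
    seq, windows, _, _ = battery
    return extract_features(seq, windows)


@pytest.fixture()
def cfg():
    return FeatureConfig()


def make_sequence(per_joint_positions, fps=30.0):
    """Build a SkeletonSequence over the canonical joints.

    ``per_joint_positions`` maps joint name -> (n, 3) array; joints not
    named rest at distinct fixed offsets so they are tracked but still.
    """
    n = len(next(iter(per_joint_positions.values())))
    pos = np.zeros((n, len(CANONICAL_JOINTS), 3))
    for j, name in enumerate(CANONICAL_JOINTS):
        if name in per_joint_positions:
            pos[:, j, :] = np.asarray(per_joint_positions[name], dtype=float)
        else:
            pos[:, j, :] = [0.0, 0.01 * j, 0.0]
    return SkeletonSequence(positions=pos, fps=fps, joints=CANONICAL_JOINTS)


def speed_fourth_order(track, fps):
    """Per-frame speed via 4th-order central differences (interior only).

    Second-order differences carry an O(v''/ (n)^2) bias at a velocity
    peak, too coarse to verify the analytic minimum-jerk peak speed; the
    5-point stencil reduces the truncation error to O(h^4).
    """
    x = np.asarray(track, dtype=float)
    v = (-x[4:] + 8 * x[3:-1] - 8 * x[1:-3] + x[:-4]) * (fps / 12.0)
    return np.linalg.norm(v, axis=1)


def still_run_sequence(run_frames, n_total=40, start=12, fps=30.0, step=0.02):
    """All hold joints move ``step`` m/frame except an exact still run.

    Frames [start, start + run_frames) are stationary; every other
    consecutive-frame displacement is ``step``.
    """
    x = np.empty(n_total)
    x[0] = 0.0
    for i in range(1, n_total):
        inside = start < i < start + run_frames  # displacement into frame i is zero
        x[i] = x[i - 1] + (0.0 if inside else step)
    pos = {}
    from gesturekin import HOLD_JOINTS

    for k, joint in enumerate(HOLD_JOINTS):
        track = np.stack([x, np.full(n_total, 0.1 * k), np.zeros(n_total)], axis=1)
        pos[joint] = track
    return make_sequence(pos, fps=fps)
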