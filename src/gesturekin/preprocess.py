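"""Trajectory smoothing, speed computation and act slicing.

Raw markerless tracking carries frame-level jitter, so every coordinate is
smoothed with a Savitzky–Golay filter (15-frame window, degree-5
polynomial by default) before any feature is computed.  Speeds are then
central differences of the smoothed positions, and acts are cut out of
the smoothed recording using the half-open frame convention.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .skeleton_io import ActWindow, SkeletonSequence

__all__ = ["SmoothingConfig", "SpeedSeries", "smooth_positions", "compute_speed", "slice_act"]


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky–Golay parameters: odd ``window`` (frames) and polynomial ``degree``."""

    window: int = 15
    degree: int = 5

    def __post_init__(self) -> None:
        if self.window <= 0 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd positive integer, got {self.window}")
        if not 0 < self.degree < self.window:
            raise ValueError(
                f"degree must satisfy 0 < degree < window, got degree={self.degree}, "
                f"window={self.window}"
            )


@dataclass(frozen=True)
class SpeedSeries:
    """Per-frame scalar speed (m/s) of one joint."""

    joint: str
    fps: float
    speed: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.speed, dtype=float)
        if s.ndim != 1:
            raise ValueError("speed must be one-dimensional")
        if s.size and np.nanmin(s) < 0:
            raise ValueError("speed must be nonnegative")
        object.__setattr__(self, "speed", s)

    @property
    def n_frames(self) -> int:
        return self.speed.size


def smooth_positions(seq: SkeletonSequence, cfg: SmoothingConfig = SmoothingConfig()) -> SkeletonSequence:
    """Smooth every joint coordinate independently with a Savitzky–Golay filter.

    Each x/y/z series is replaced by the value of a local least-squares
    polynomial of ``cfg.degree`` fitted over ``cfg.window`` frames.  The
    filter therefore passes polynomial trajectories of degree <= cfg.degree
    unchanged at interior frames.  Edges use mirror padding so the output
    has the same length and stays aligned with the video frames.

    Missing (NaN) samples must be handled upstream: smoothing across a gap
    would silently invent positions.
    """
    if seq.n_frames < cfg.window:
        raise ValueError(
            f"recording has {seq.n_frames} frames but the smoothing window is "
            f"{cfg.window}; use a shorter window or a longer recording"
        )
    if np.isnan(seq.positions).any():
        bad = [seq.joints[j] for j in np.unique(np.argwhere(np.isnan(seq.positions))[:, 1])]
        raise ValueError(
            f"cannot smooth across missing samples (joints: {', '.join(bad)}); "
            "drop or fill untracked spans first"
        )
    smoothed = savgol_filter(
        seq.positions, window_length=cfg.window, polyorder=cfg.degree, axis=0, mode="mirror"
    )
    return SkeletonSequence(positions=smoothed, fps=seq.fps, joints=seq.joints)


def compute_speed(seq: SkeletonSequence, joint: str) -> SpeedSeries:
    """Scalar speed (m/s) of one joint per frame.

    Central differences of position at interior frames, one-sided
    differences at the two endpoints (numpy.gradient), then the Euclidean
    norm over x/y/z.
    """
    pos = seq.get(joint)
    if np.isnan(pos).any():
        raise ValueError(f"joint {joint!r} has missing samples; speed is undefined there")
    if seq.n_frames < 2:
        return SpeedSeries(joint=joint, fps=seq.fps, speed=np.zeros(seq.n_frames))
    vel = np.gradient(pos, 1.0 / seq.fps, axis=0)
    return SpeedSeries(joint=joint, fps=seq.fps, speed=np.linalg.norm(vel, axis=1))


def slice_act(seq: SkeletonSequence, window: ActWindow) -> SkeletonSequence:
    """Cut the frames [onset_frame, offset_frame) of one act out of a recording."""
    start, stop = window.frame_span(seq.fps)
    if stop > seq.n_frames:
        raise ValueError(
            f"act {window.label!r} runs to {window.offset_s} s but the recording "
            f"lasts only {seq.duration_s:.3f} s"
        )
    return SkeletonSequence(positions=seq.positions[start:stop], fps=seq.fps, joints=seq.joints)
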