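"""Velocity-profile plots and stick-figure skeleton renders.

The velocity-profile plot shows each hand's speed against time with the
submovement cutoff as a horizontal line, an X marker at each counted
submovement peak, and a shaded, numbered span per hold.  Every plot is
accompanied by a JSON sidecar manifest describing exactly what was
drawn, generated from the same feature objects that fill the feature
table, so downstream checks never have to parse pixels.

Skeleton renders draw the torso, arms and head as green lines on a black
background, one image per frame, using an orthographic projection onto
the x-y plane (a configurable rotation about the vertical axis selects
other viewing angles).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .features import ActAnalysis, FeatureConfig, Hold, Submovement
from .joints import BONES
from .skeleton_io import SkeletonSequence

__all__ = ["ProfilePlotSpec", "plot_velocity_profile", "render_skeleton_frames", "frames_to_video"]


@dataclass
class ProfilePlotSpec:
    """Everything one velocity-profile figure shows."""

    fps: float
    speeds: Dict[str, np.ndarray]  # hand label -> per-frame speed (m/s)
    submovements: Dict[str, List[Submovement]] = field(default_factory=dict)
    holds: List[Hold] = field(default_factory=list)
    threshold: float = 0.2  # m/s cutoff line
    title: str = ""

    @classmethod
    def from_analysis(cls, analysis: ActAnalysis, cfg: FeatureConfig = FeatureConfig()) -> "ProfilePlotSpec":
        """Build the plot spec from the same objects written to the feature table."""
        speeds = {h: s.speed for h, s in analysis.speeds.items()}
        fps = next(iter(analysis.speeds.values())).fps
        return cls(
            fps=fps,
            speeds=speeds,
            submovements=analysis.submovements,
            holds=analysis.holds,
            threshold=cfg.submovement_min_peak,
            title=analysis.label,
        )

    def validate(self) -> int:
        if not self.speeds:
            raise ValueError("profile plot needs at least one speed series")
        n = {len(s) for s in self.speeds.values()}
        if len(n) != 1 or 0 in n:
            raise ValueError("speed series must be nonempty and equal-length")
        n_frames = n.pop()
        for subs in self.submovements.values():
            for sm in subs:
                if not 0 <= sm.peak_frame < n_frames:
                    raise ValueError(f"submovement peak frame {sm.peak_frame} outside act")
        for h in self.holds:
            if not 0 <= h.start_frame < h.end_frame <= n_frames:
                raise ValueError(f"hold [{h.start_frame}, {h.end_frame}) outside act")
        return n_frames


def plot_velocity_profile(spec: ProfilePlotSpec, path: Union[str, Path]) -> Path:
    """Write the velocity-profile figure and its JSON manifest.

    Returns the manifest path (``<path>.json``).
    """
    n_frames = spec.validate()
    path = Path(path)
    t = np.arange(n_frames) / spec.fps

    fig, ax = plt.subplots(figsize=(9, 4))
    colors = {"L": "tab:blue", "R": "tab:green"}
    for hand, speed in sorted(spec.speeds.items()):
        ax.plot(t, speed, color=colors.get(hand, None), label=f"{hand} hand")
    ax.axhline(spec.threshold, color="red", lw=2, label=f"cutoff {spec.threshold} m/s")
    manifest = {
        "n_frames": n_frames,
        "fps": spec.fps,
        "threshold_mps": spec.threshold,
        "peaks": [],
        "holds": [],
    }
    for hand, subs in sorted(spec.submovements.items()):
        for sm in subs:
            ax.plot(sm.peak_frame / spec.fps, sm.peak_speed, "x", color="red", ms=10, mew=2)
            manifest["peaks"].append(
                {
                    "hand": hand,
                    "time_s": sm.peak_frame / spec.fps,
                    "speed_mps": sm.peak_speed,
                    "onset_s": sm.onset_frame / spec.fps,
                    "offset_s": sm.offset_frame / spec.fps,
                }
            )
    for i, h in enumerate(spec.holds, start=1):
        a, b = h.start_frame / spec.fps, h.end_frame / spec.fps
        ax.axvspan(a, b, color="0.8", zorder=0)
        ax.text((a + b) / 2, ax.get_ylim()[1] * 0.9, str(i), ha="center", color="0.3")
        manifest["holds"].append({"index": i, "start_s": a, "end_s": b, "duration_s": h.duration_s})
    ax.set_xlabel("time (s)")
    ax.set_ylabel("velocity (m/s)")
    if spec.title:
        ax.set_title(spec.title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)

    manifest_path = path.with_suffix(path.suffix + ".json")
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def _project(points: np.ndarray, rotation_deg: float) -> np.ndarray:
    """Orthographic projection onto the image plane after rotating the scene
    about the vertical axis: u = x cos(r) + z sin(r), v = y."""
    r = math.radians(rotation_deg)
    u = points[:, 0] * math.cos(r) + points[:, 2] * math.sin(r)
    return np.stack([u, points[:, 1]], axis=1)


def render_skeleton_frames(
    seq: SkeletonSequence,
    out_dir: Union[str, Path],
    rotation_deg: float = 0.0,
    prefix: str = "frame",
) -> List[Path]:
    """Render each frame as a green-on-black stick figure PNG.

    Only bones with both joints present in the sequence are drawn (torso,
    arms, head).  Returns the written paths in frame order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    jidx = seq.joint_index
    bones = [(jidx[a], jidx[b]) for a, b in BONES if a in jidx and b in jidx]
    if not bones:
        raise ValueError("no drawable bones: sequence lacks the canonical joints")

    # fixed axes limits over the whole sequence keep stationary frames identical
    proj_all = _project(seq.positions.reshape(-1, 3), rotation_deg)
    finite = proj_all[np.isfinite(proj_all).all(axis=1)]
    lo = finite.min(axis=0) - 0.1
    hi = finite.max(axis=0) + 0.1

    paths = []
    fig, ax = plt.subplots(figsize=(4, 5))
    for f in range(seq.n_frames):
        ax.clear()
        ax.set_facecolor("black")
        pts = _project(seq.positions[f], rotation_deg)
        for a, b in bones:
            ax.plot([pts[a, 0], pts[b, 0]], [pts[a, 1], pts[b, 1]], color="lime", lw=2)
        ax.set_xlim(lo[0], hi[0])
        ax.set_ylim(lo[1], hi[1])
        ax.set_aspect("equal")
        ax.set_xticks([])
        ax.set_yticks([])
        p = out_dir / f"{prefix}{f:05d}.png"
        fig.savefig(p, dpi=80, facecolor="black")
        paths.append(p)
    plt.close(fig)
    return paths


def frames_to_video(frame_paths: Sequence[Union[str, Path]], path: Union[str, Path], fps: float) -> None:
    """Assemble rendered frames into a video (requires the imageio extra)."""
    import imageio.v2 as imageio

    with imageio.get_writer(str(path), fps=fps) as w:
        for p in frame_paths:
            w.append_data(imageio.imread(str(p)))
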