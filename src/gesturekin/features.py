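"""The six per-act kinematic features.

distance
    Accumulated path length of both hands (m) over the act.
vertical amplitude
    Highest body-referenced height category (1-4) reached by the dominant
    hand: below the torso midline, between torso midline and neck, between
    neck and head, or above the head.  The comparison is frame-wise, so a
    leaning trunk is handled.
peak velocity
    Maximum speed (m/s) of the dominant hand; optionally re-expressed as a
    dataset-relative category by equal-frequency binning.
submovements
    Ballistic movement segments per hand, found as velocity peaks of at
    least 0.2 m/s that are at least 8 frames from the next retained peak.
holds
    Intervals of at least 300 ms in which hand, thumb, elbow and shoulder
    of both arms all move less than 0.01 m per frame; reported as a count
    and as total hold time (s).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import rankdata

from .exceptions import DataQualityError
from .joints import AMPLITUDE_LANDMARKS, HOLD_JOINTS, hand_joint
from .preprocess import SmoothingConfig, SpeedSeries, compute_speed, slice_act, smooth_positions
from .skeleton_io import ActWindow, SkeletonSequence

__all__ = [
    "FeatureConfig",
    "Submovement",
    "Hold",
    "ActFeatures",
    "ActAnalysis",
    "FeatureTable",
    "detect_submovements",
    "detect_holds",
    "vertical_amplitude",
    "peak_velocity",
    "bin_peak_velocities",
    "accumulated_distance",
    "hold_time",
    "hold_min_frames",
    "analyze_act",
    "extract_features",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds and joint choices for feature extraction.

    Defaults are the published operationalization: a submovement peak must
    reach 0.2 m/s and be at least 8 frames from the next nearest peak; a
    hold requires every hold joint to move less than 0.01 m per frame for
    at least 300 ms; peak velocities are binned into 7 dataset-relative
    categories.
    """

    submovement_min_peak: float = 0.2  # m/s
    submovement_min_separation: int = 8  # frames
    boundary_speed: float = 0.05  # m/s, near-zero threshold for on/offsets
    hold_max_displacement: float = 0.01  # m per frame
    hold_min_duration: float = 0.300  # s
    velocity_bins: int = 7
    velocity_bin_mode: str = "quantile"  # or "width"
    dominant_hand: str = "R"
    hold_joints: Tuple[str, ...] = HOLD_JOINTS
    amplitude_landmarks: Tuple[str, ...] = AMPLITUDE_LANDMARKS

    def __post_init__(self) -> None:
        for name in (
            "submovement_min_peak",
            "boundary_speed",
            "hold_max_displacement",
            "hold_min_duration",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.submovement_min_separation < 1:
            raise ValueError("submovement_min_separation must be >= 1 frame")
        if self.velocity_bins < 2:
            raise ValueError("velocity_bins must be >= 2")
        if self.velocity_bin_mode not in ("quantile", "width"):
            raise ValueError("velocity_bin_mode must be 'quantile' or 'width'")
        if self.dominant_hand not in ("L", "R"):
            raise ValueError("dominant_hand must be 'L' or 'R'")
        if len(self.amplitude_landmarks) != 3:
            raise ValueError("amplitude_landmarks must name three joints, bottom to top")


@dataclass(frozen=True)
class Submovement:
    """One ballistic segment: a velocity bell with its peak and extent."""

    hand: str
    peak_frame: int
    peak_speed: float
    onset_frame: int
    offset_frame: int

    def __post_init__(self) -> None:
        if not self.onset_frame <= self.peak_frame <= self.offset_frame:
            raise ValueError("submovement frames must satisfy onset <= peak <= offset")


@dataclass(frozen=True)
class Hold:
    """A maximal still interval, half-open in frames."""

    start_frame: int
    end_frame: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("hold must span at least one frame")


@dataclass
class ActFeatures:
    """The computed feature record for one act (one feature-table row)."""

    label: str
    distance_m: float = math.nan
    vertical_amplitude: Optional[int] = None
    peak_velocity_mps: float = math.nan
    peak_velocity_bin: Optional[int] = None
    submovements_left: Optional[int] = None
    submovements_right: Optional[int] = None
    submovements_total: Optional[int] = None
    hold_count: Optional[int] = None
    hold_time_s: float = math.nan
    distance_left_m: float = math.nan
    distance_right_m: float = math.nan
    error: Optional[str] = None


@dataclass
class ActAnalysis:
    """Per-act detail behind one feature row; the single source the plots use."""

    label: str
    features: ActFeatures
    speeds: Dict[str, SpeedSeries] = field(default_factory=dict)
    submovements: Dict[str, List[Submovement]] = field(default_factory=dict)
    holds: List[Hold] = field(default_factory=list)


@dataclass
class FeatureTable:
    """Ordered per-act feature records, one row per act."""

    rows: List[ActFeatures]
    analyses: List[ActAnalysis] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "act_label": r.label,
                    "distance_m": r.distance_m,
                    "vertical_amplitude": r.vertical_amplitude,
                    "peak_velocity_mps": r.peak_velocity_mps,
                    "peak_velocity_bin": r.peak_velocity_bin,
                    "submovements_left": r.submovements_left,
                    "submovements_right": r.submovements_right,
                    "submovements_total": r.submovements_total,
                    "hold_count": r.hold_count,
                    "hold_time_s": r.hold_time_s,
                    "distance_left_m": r.distance_left_m,
                    "distance_right_m": r.distance_right_m,
                    "error": r.error,
                }
            )
        return pd.DataFrame(recs)

    def __len__(self) -> int:
        return len(self.rows)


def detect_submovements(speed: SpeedSeries, cfg: FeatureConfig = FeatureConfig()) -> List[Submovement]:
    """Velocity-peak analysis of one hand's speed series.

    Local maxima with ``peak_speed >= submovement_min_peak`` are retained
    greedily in descending height (earlier peak wins a height tie) under
    the constraint that retained peaks are at least
    ``submovement_min_separation`` frames apart.  Each retained peak's
    onset and offset are found by scanning outward to the first frame
    below ``boundary_speed`` or the first deceleration-to-acceleration
    reversal (a local speed minimum).
    """
    s = speed.speed
    if s.size == 0:
        return []
    candidates = [p for p in find_peaks(s)[0] if s[p] >= cfg.submovement_min_peak]
    kept: List[int] = []
    for p in sorted(candidates, key=lambda p: (-s[p], p)):
        if all(abs(p - q) >= cfg.submovement_min_separation for q in kept):
            kept.append(p)
    kept.sort()

    hand = "L" if speed.joint.endswith("Left") else "R" if speed.joint.endswith("Right") else ""
    out = []
    for p in kept:
        onset = p
        while onset > 0:
            j = onset - 1
            if s[j] < cfg.boundary_speed:
                onset = j
                break
            if j > 0 and s[j - 1] >= s[j] <= s[onset]:  # local minimum: reversal
                onset = j
                break
            onset = j
        offset = p
        n = s.size
        while offset < n - 1:
            j = offset + 1
            if s[j] < cfg.boundary_speed:
                offset = j
                break
            if j < n - 1 and s[offset] >= s[j] <= s[j + 1]:
                offset = j
                break
            offset = j
        out.append(
            Submovement(
                hand=hand, peak_frame=int(p), peak_speed=float(s[p]),
                onset_frame=int(onset), offset_frame=int(offset),
            )
        )
    return out


def hold_min_frames(cfg: FeatureConfig, fps: float) -> int:
    """Minimum frame span of a hold: ceil(hold_min_duration * fps); 9 at 30 fps."""
    return int(math.ceil(cfg.hold_min_duration * fps - 1e-9))


def detect_holds(seq: SkeletonSequence, cfg: FeatureConfig = FeatureConfig()) -> List[Hold]:
    """Find maximal still intervals of at least ``hold_min_duration``.

    A consecutive-frame displacement is "still" when every hold joint
    (hand, thumb, elbow, shoulder of both arms) moved less than
    ``hold_max_displacement`` meters.  A maximal run of k still
    displacements spans k+1 frames; runs spanning at least
    ``hold_min_frames`` frames become holds, so 9 stationary frames at
    30 fps (= 300 ms) yield exactly one hold and 8 yield none.
    """
    tracks = []
    for joint in cfg.hold_joints:
        if not seq.has_joint(joint):
            raise DataQualityError(f"hold detection requires joint {joint!r}, absent from recording")
        pos = seq.get(joint)
        if np.isnan(pos).any():
            raise DataQualityError(f"hold joint {joint!r} has missing samples")
        tracks.append(pos)
    n = seq.n_frames
    if n < 2:
        return []
    disp = np.max(
        [np.linalg.norm(np.diff(t, axis=0), axis=1) for t in tracks], axis=0
    )  # length n-1; disp[i] is the move into frame i+1
    still = disp < cfg.hold_max_displacement

    min_frames = hold_min_frames(cfg, seq.fps)
    holds: List[Hold] = []
    i = 0
    while i < still.size:
        if still[i]:
            j = i
            while j + 1 < still.size and still[j + 1]:
                j += 1
            start, end = i, j + 2  # frames [i, j+2): j-i+1 displacements span j-i+2 frames
            span = end - start
            if span >= min_frames:
                holds.append(Hold(start_frame=start, end_frame=end, duration_s=span / seq.fps))
            i = j + 1
        i += 1
    return holds


def vertical_amplitude(seq: SkeletonSequence, cfg: FeatureConfig = FeatureConfig()) -> int:
    """Highest body-referenced height category (1-4) of the dominant hand.

    Per frame: 1 if the hand is below the torso-midline landmark, 2 up to
    the neck, 3 up to the head, 4 at or above the head; the act's value is
    the maximum over frames.  If the landmark heights are not in
    increasing order in more than half the frames, a posture-quality
    warning is issued and the computation proceeds.
    """
    hand = seq.get(hand_joint(cfg.dominant_hand))[:, 1]
    lo, mid, hi = (seq.get(j)[:, 1] for j in cfg.amplitude_landmarks)
    for name, arr in zip(("hand",) + tuple(cfg.amplitude_landmarks), (hand, lo, mid, hi)):
        if np.isnan(arr).any():
            raise DataQualityError(f"vertical amplitude: joint {name!r} has missing samples")
    disordered = np.mean(~((lo < mid) & (mid < hi)))
    if disordered > 0.5:
        warnings.warn(
            f"amplitude landmarks out of vertical order in {disordered:.0%} of frames; "
            "posture may be invalid",
            stacklevel=2,
        )
    cat = np.ones(seq.n_frames, dtype=int)
    cat[hand >= lo] = 2
    cat[hand >= mid] = 3
    cat[hand >= hi] = 4
    return int(cat.max())


def peak_velocity(speed: SpeedSeries) -> float:
    """Maximum of the speed series (m/s)."""
    if speed.n_frames == 0:
        raise ValueError("peak velocity of an empty speed series is undefined")
    return float(speed.speed.max())


def bin_peak_velocities(values: Sequence[float], k: int = 7, mode: str = "quantile") -> np.ndarray:
    """Dataset-relative categories 1..k for a collection of peak velocities.

    ``quantile`` (default) gives equal-frequency bins across the supplied
    dataset; ``width`` gives equal-width bins over the observed range.
    Bins are monotone in value and ties share the lower bin.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot bin an empty collection")
    if k < 2:
        raise ValueError("need at least 2 bins")
    if np.unique(v).size < k:
        warnings.warn(
            f"only {np.unique(v).size} distinct values for {k} bins; some bins will be empty",
            stacklevel=2,
        )
    if mode == "quantile":
        ranks = rankdata(v, method="min")
        bins = np.ceil(ranks * k / v.size).astype(int)
    elif mode == "width":
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.ones(v.size, dtype=int)
        bins = np.floor((v - lo) / (hi - lo) * k).astype(int) + 1
    else:
        raise ValueError("mode must be 'quantile' or 'width'")
    return np.clip(bins, 1, k)


def accumulated_distance(seq: SkeletonSequence, hand: Optional[str] = None) -> float:
    """Accumulated path length (m) of the hands over the act.

    Sum of frame-to-frame Euclidean displacements, over both hands by
    default or one hand when ``hand`` is 'L' or 'R'.
    """
    hands = ("L", "R") if hand is None else (hand,)
    total = 0.0
    for h in hands:
        joint = hand_joint(h)
        if not seq.has_joint(joint):
            raise DataQualityError(f"distance requires joint {joint!r}, absent from recording")
        pos = seq.get(joint)
        if np.isnan(pos).any():
            raise DataQualityError(f"distance: joint {joint!r} has missing samples")
        total += float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())
    return total


def hold_time(holds: Sequence[Hold]) -> float:
    """Total holding time (s): the sum of hold durations, 0 if none."""
    ordered = sorted(holds, key=lambda h: h.start_frame)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_frame < a.end_frame:
            raise ValueError("holds must be pairwise disjoint")
    return float(sum(h.duration_s for h in holds))


def analyze_act(seq: SkeletonSequence, label: str, cfg: FeatureConfig = FeatureConfig()) -> ActAnalysis:
    """Compute all features for one already-smoothed, already-sliced act."""
    speeds = {h: compute_speed(seq, hand_joint(h)) for h in ("L", "R")}
    subs = {h: detect_submovements(speeds[h], cfg) for h in ("L", "R")}
    holds = detect_holds(seq, cfg)
    dist_l = accumulated_distance(seq, "L")
    dist_r = accumulated_distance(seq, "R")
    feats = ActFeatures(
        label=label,
        distance_m=dist_l + dist_r,
        vertical_amplitude=vertical_amplitude(seq, cfg),
        peak_velocity_mps=peak_velocity(speeds[cfg.dominant_hand]),
        submovements_left=len(subs["L"]),
        submovements_right=len(subs["R"]),
        submovements_total=len(subs["L"]) + len(subs["R"]),
        hold_count=len(holds),
        hold_time_s=hold_time(holds),
        distance_left_m=dist_l,
        distance_right_m=dist_r,
    )
    return ActAnalysis(label=label, features=feats, speeds=speeds, submovements=subs, holds=holds)


def extract_features(
    seq: SkeletonSequence,
    windows: Optional[Sequence[ActWindow]] = None,
    cfg: FeatureConfig = FeatureConfig(),
    smoothing: SmoothingConfig = SmoothingConfig(),
) -> FeatureTable:
    """The full pipeline: smooth, segment into acts, compute all features.

    The whole recording is smoothed once, then cut per act window (or
    treated as a single act when no windows are given).  A data-quality
    problem in one act is recorded in that act's row and processing
    continues.  Peak-velocity bins are dataset-relative, so they are
    assigned only when the table has at least two acts.
    """
    smoothed = smooth_positions(seq, smoothing)
    rows: List[ActFeatures] = []
    analyses: List[ActAnalysis] = []
    for w in windows if windows is not None else [None]:
        label = "all" if w is None else w.label
        try:
            act_seq = smoothed if w is None else slice_act(smoothed, w)
            analysis = analyze_act(act_seq, label, cfg)
        except (DataQualityError, ValueError) as exc:
            analysis = ActAnalysis(label=label, features=ActFeatures(label=label, error=str(exc)))
        rows.append(analysis.features)
        analyses.append(analysis)

    ok = [r for r in rows if r.error is None]
    if len(ok) >= 2:
        bins = bin_peak_velocities(
            [r.peak_velocity_mps for r in ok], cfg.velocity_bins, cfg.velocity_bin_mode
        )
        for r, b in zip(ok, bins):
            r.peak_velocity_bin = int(b)
    return FeatureTable(rows=rows, analyses=analyses)
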