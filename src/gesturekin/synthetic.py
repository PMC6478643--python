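"""Synthetic skeleton recordings with known ground truth.

Acts are assembled from three ingredients:

* **Strokes** — straight-line minimum-jerk hand movements (the standard
  model of ballistic reaching segments: a velocity bell with zero
  velocity and acceleration at both ends, peak speed 1.875 * D / T for
  amplitude D and duration T).  The wrist, hand tip and thumb ride
  rigidly with the hand; the elbow moves half as far.
* **Sway** — a slow circular weight-shifting drift of the shoulders and
  elbows in the horizontal plane, generated as a gated velocity field so
  its frame-to-frame displacement is nearly constant and well above the
  hold stillness threshold.  Without it, every pause between strokes
  would register as a hold; with it, stillness occurs only where it is
  scheduled.
* **Holds** — windows in which the sway velocity is ramped smoothly to
  zero and every joint freezes.

Ground-truth annotations are computed from the raw noise-free trajectory
(stroke arithmetic for submovements, amplitude and distance; a
generator-local run-length scan for holds), independent of the feature
extraction path, which operates on the Savitzky-Golay-smoothed data.
Because smooth stops pass through a sub-threshold velocity band, realized
still intervals can exceed the scheduled freeze window by a frame or two
per side; the ground truth records the realized interval.

Optional i.i.d. Gaussian jitter per coordinate per frame emulates raw
sensor noise and is added after the ground truth is computed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .exceptions import SpecError
from .features import FeatureConfig, Hold, hold_min_frames
from .joints import CANONICAL_JOINTS, hand_joint
from .skeleton_io import (
    ActWindow,
    SkeletonSequence,
    time_to_frame,
    write_act_windows,
    write_skeleton_table,
)

__all__ = [
    "MINIMUM_JERK_PEAK_FACTOR",
    "Posture",
    "Stroke",
    "ActSpec",
    "GroundTruth",
    "minimum_jerk_segment",
    "generate_act",
    "generate_dataset",
]

#: Peak speed of a minimum-jerk segment of amplitude D and duration T is
#: this factor times D / T (maximum of 30 * tau^2 * (1 - tau)^2 at tau = 1/2).
MINIMUM_JERK_PEAK_FACTOR = 1.875


def _mj(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile 10 t^3 - 15 t^4 + 6 t^5 on [0, 1]."""
    tau = np.asarray(tau, dtype=float)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def minimum_jerk_segment(
    start: Sequence[float], end: Sequence[float], duration_s: float, fps: float
) -> np.ndarray:
    """Sample a straight minimum-jerk trajectory at the frame grid.

    Returns positions of shape (n_steps + 1, 3) covering t = 0 .. duration
    inclusive, where n_steps = round(duration_s * fps) must be >= 2.  The
    endpoints are reproduced exactly and the velocity is zero at both.
    """
    n_steps = int(round(duration_s * fps))
    if n_steps < 2:
        raise SpecError(
            f"stroke duration {duration_s} s is under 2 frames at {fps} fps"
        )
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    tau = np.arange(n_steps + 1) / n_steps
    return start[None, :] + _mj(tau)[:, None] * (end - start)[None, :]


@dataclass(frozen=True)
class Posture:
    """Resting upper-body layout, parameterized by the landmark heights (m)."""

    spine_mid_y: float = 1.05
    neck_y: float = 1.35
    head_y: float = 1.50

    def __post_init__(self) -> None:
        if not self.spine_mid_y < self.neck_y < self.head_y:
            raise SpecError("landmark heights must increase: SpineMid < Neck < Head")

    def layout(self) -> Dict[str, np.ndarray]:
        """Resting 3-D position of every canonical joint."""
        mid, neck, head = self.spine_mid_y, self.neck_y, self.head_y
        shoulder_y = neck - 0.05
        pts = {
            "SpineBase": (0.0, mid - 0.20, 0.0),
            "SpineMid": (0.0, mid, 0.0),
            "SpineShoulder": (0.0, shoulder_y, 0.0),
            "Neck": (0.0, neck, 0.0),
            "Head": (0.0, head, 0.0),
        }
        for side, sx in (("Left", -1.0), ("Right", 1.0)):
            pts[f"Shoulder{side}"] = (sx * 0.20, shoulder_y, 0.0)
            pts[f"Elbow{side}"] = (sx * 0.28, mid, 0.05)
            pts[f"Wrist{side}"] = (sx * 0.30, mid - 0.17, 0.18)
            pts[f"Hand{side}"] = (sx * 0.30, mid - 0.20, 0.25)
            pts[f"HandTip{side}"] = (sx * 0.30, mid - 0.22, 0.32)
            pts[f"Thumb{side}"] = (sx * 0.26, mid - 0.21, 0.28)
        return {k: np.asarray(v, dtype=float) for k, v in pts.items()}

    def rest_hand(self, hand: str) -> np.ndarray:
        return self.layout()[hand_joint(hand)]


@dataclass(frozen=True)
class Stroke:
    """One ballistic hand movement: ``hand`` moves to ``end`` starting at
    ``start_s`` over ``duration_s`` seconds.  ``start`` is optional; when
    given it must match the hand's current position (no teleports)."""

    hand: str
    start_s: float
    duration_s: float
    end: Tuple[float, float, float]
    start: Optional[Tuple[float, float, float]] = None


@dataclass
class ActSpec:
    """Full specification of one synthetic recording."""

    duration_s: float
    fps: float = 30.0
    posture: Posture = field(default_factory=Posture)
    strokes: List[Stroke] = field(default_factory=list)
    holds: List[Tuple[float, float]] = field(default_factory=list)  # (start_s, duration_s)
    jitter_sd: float = 0.0
    seed: int = 0
    sway_speed: float = 0.9  # m/s tangential speed of the shoulder sway
    sway_period_s: float = 0.8
    sway_ramp_s: float = 0.2
    sway_leak: float = 0.6  # 1/s restoring rate bounding the sway drift

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class GroundTruth:
    """The generator's known annotations for one act."""

    label: str
    submovements: Dict[str, int]
    peak_frames: Dict[str, List[int]]
    holds: List[Hold]
    hold_count: int
    hold_time_s: float
    vertical_amplitude: int
    peak_speed_mps: float
    distance_m: float
    distance_left_m: float
    distance_right_m: float


@dataclass
class _StrokeEvent:
    hand: str
    f0: int
    f1: int
    amplitude_m: float
    peak_speed: float
    peak_frame: int
    end_y: float
    start_y: float


def _validate_spec(spec: ActSpec) -> None:
    if spec.duration_s <= 0 or spec.fps <= 0:
        raise SpecError("duration_s and fps must be positive")
    if spec.jitter_sd < 0:
        raise SpecError("jitter_sd must be nonnegative")
    holds = sorted(spec.holds)
    for (a, d) in holds:
        if d <= 0:
            raise SpecError(f"hold at {a} s has nonpositive duration {d}")
        if a - spec.sway_ramp_s < 0 or a + d + spec.sway_ramp_s > spec.duration_s:
            raise SpecError(f"hold at {a} s (plus sway ramps) exceeds the recording")
    for (a1, d1), (a2, d2) in zip(holds, holds[1:]):
        if a2 - spec.sway_ramp_s < a1 + d1 + spec.sway_ramp_s:
            raise SpecError(f"holds at {a1} s and {a2} s overlap (including sway ramps)")
    for st in spec.strokes:
        if st.start_s < 0 or st.start_s + st.duration_s > spec.duration_s:
            raise SpecError(f"stroke at {st.start_s} s exceeds the recording")
        for (a, d) in holds:
            if st.start_s < a + d and a < st.start_s + st.duration_s:
                raise SpecError(
                    f"stroke at {st.start_s} s overlaps the hold at {a} s; "
                    "holds must freeze all joints"
                )


def _hand_offsets(
    spec: ActSpec, hand: str, rest: np.ndarray
) -> Tuple[np.ndarray, List[_StrokeEvent]]:
    """Cumulative displacement of one hand over the recording, plus events."""
    n = spec.n_frames
    off = np.zeros((n, 3))
    events: List[_StrokeEvent] = []
    cur = rest.copy()
    cum = np.zeros(3)
    prev_f1 = 0
    for st in sorted((s for s in spec.strokes if s.hand == hand), key=lambda s: s.start_s):
        f0 = time_to_frame(st.start_s, spec.fps)
        n_steps = int(round(st.duration_s * spec.fps))
        if n_steps < 2:
            raise SpecError(f"stroke at {st.start_s} s is under 2 frames")
        f1 = f0 + n_steps
        if f0 < prev_f1:
            raise SpecError(f"strokes of hand {hand!r} overlap near {st.start_s} s")
        if f1 >= n:
            raise SpecError(f"stroke at {st.start_s} s runs past the recording")
        end = np.asarray(st.end, dtype=float)
        if st.start is not None and not np.allclose(st.start, cur, atol=1e-9):
            raise SpecError(
                f"stroke at {st.start_s} s starts at {st.start} but the hand is at "
                f"{tuple(cur)}; strokes must chain continuously"
            )
        delta = end - cur
        prof = _mj(np.arange(n_steps + 1) / n_steps)
        off[f0 : f1 + 1] = cum[None, :] + prof[:, None] * delta[None, :]
        off[f1 + 1 :] = cum + delta
        amp = float(np.linalg.norm(delta))
        dur = n_steps / spec.fps
        events.append(
            _StrokeEvent(
                hand=hand,
                f0=f0,
                f1=f1,
                amplitude_m=amp,
                peak_speed=MINIMUM_JERK_PEAK_FACTOR * amp / dur,
                peak_frame=f0 + n_steps // 2,
                start_y=float(cur[1]),
                end_y=float(end[1]),
            )
        )
        cum = cum + delta
        cur = end.copy()
        prev_f1 = f1
    return off, events


def _sway_offsets(spec: ActSpec) -> np.ndarray:
    """Shoulder/elbow sway offset per frame, frozen inside each hold.

    The sway is a circular velocity field (constant tangential speed, so
    the frame-to-frame displacement is uniform around the circle) gated
    by a smooth 0-1 envelope that drops to zero over ``sway_ramp_s``
    before each hold and rises after it.  Gating the *velocity* rather
    than the position keeps the stillness-threshold crossing sharp: the
    displacement scale (sway_speed / fps, about 0.03 m) is far above the
    0.01 m hold threshold, so only a fraction of a frame sits in the
    ambiguous band.  A weak restoring leak bounds the drift that gating
    episodes would otherwise accumulate.
    """
    n = spec.n_frames
    t = np.arange(n) / spec.fps
    gate = np.ones(n)
    r = spec.sway_ramp_s
    for (a, d) in spec.holds:
        h = np.zeros(n)
        up = (t >= a - r) & (t < a)
        h[up] = _mj((t[up] - (a - r)) / r)
        h[(t >= a) & (t < a + d)] = 1.0
        dn = (t >= a + d) & (t < a + d + r)
        h[dn] = 1.0 - _mj((t[dn] - (a + d)) / r)
        gate *= 1.0 - h

    omega = 2.0 * np.pi / spec.sway_period_s
    vx = spec.sway_speed * np.cos(omega * t)
    vz = -spec.sway_speed * np.sin(omega * t)
    off = np.zeros((n, 3))
    z = np.zeros(3)
    for i in range(n - 1):
        v = gate[i] * np.array([vx[i], 0.0, vz[i]]) - spec.sway_leak * gate[i] * z
        z = z + v / spec.fps
        off[i + 1] = z
    return off


def _render_raw(spec: ActSpec) -> Tuple[np.ndarray, List[_StrokeEvent]]:
    """Noise-free positions (n_frames, 17, 3) plus the realized stroke events."""
    _validate_spec(spec)
    layout = spec.posture.layout()
    n = spec.n_frames
    pos = np.empty((n, len(CANONICAL_JOINTS), 3))
    for j, name in enumerate(CANONICAL_JOINTS):
        pos[:, j, :] = layout[name]

    jidx = {name: j for j, name in enumerate(CANONICAL_JOINTS)}
    events: List[_StrokeEvent] = []
    for side, h in (("Left", "L"), ("Right", "R")):
        off, ev = _hand_offsets(spec, h, layout[f"Hand{side}"])
        events.extend(ev)
        for joint in (f"Hand{side}", f"Wrist{side}", f"HandTip{side}", f"Thumb{side}"):
            pos[:, jidx[joint], :] += off
        pos[:, jidx[f"Elbow{side}"], :] += 0.5 * off

    sway = _sway_offsets(spec)
    for joint in ("ShoulderLeft", "ShoulderRight", "ElbowLeft", "ElbowRight"):
        pos[:, jidx[joint], :] += sway
    return pos, events


def _raw_still_holds(
    positions: np.ndarray, fps: float, cfg: FeatureConfig
) -> List[Hold]:
    """Generator-side hold annotation from raw positions.

    A vectorized run-length scan over sub-threshold displacements of the
    hold joints; deliberately a separate code path from the detector.
    """
    jidx = {name: j for j, name in enumerate(CANONICAL_JOINTS)}
    tracks = positions[:, [jidx[j] for j in cfg.hold_joints], :]
    if tracks.shape[0] < 2:
        return []
    disp = np.linalg.norm(np.diff(tracks, axis=0), axis=2).max(axis=1)
    still = disp < cfg.hold_max_displacement
    edges = np.diff(np.concatenate(([0], still.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    min_frames = hold_min_frames(cfg, fps)
    holds = []
    for s, e in zip(starts, stops):
        span = (e - s) + 1  # k still displacements span k+1 frames
        if span >= min_frames:
            holds.append(Hold(start_frame=int(s), end_frame=int(s + span), duration_s=span / fps))
    return holds


def _amplitude_category(max_y: float, posture: Posture) -> int:
    return 1 + sum(
        max_y >= b for b in (posture.spine_mid_y, posture.neck_y, posture.head_y)
    )


def _truth_for_span(
    label: str,
    events: Sequence[_StrokeEvent],
    raw: np.ndarray,
    spec: ActSpec,
    cfg: FeatureConfig,
    f_lo: int,
    f_hi: int,
) -> GroundTruth:
    """Ground truth for frames [f_lo, f_hi) of the raw recording."""
    inside = [e for e in events if f_lo <= e.f0 and e.f1 < f_hi]
    sub_counts = {"L": 0, "R": 0}
    peak_frames: Dict[str, List[int]] = {"L": [], "R": []}
    dist = {"L": 0.0, "R": 0.0}
    dom_speeds = [0.0]
    rest_y = {h: float(spec.posture.rest_hand(h)[1]) for h in ("L", "R")}
    max_y = rest_y[cfg.dominant_hand]
    for e in sorted(inside, key=lambda e: e.f0):
        dist[e.hand] += e.amplitude_m
        if e.peak_speed >= cfg.submovement_min_peak:
            sub_counts[e.hand] += 1
            peak_frames[e.hand].append(e.peak_frame - f_lo)
        if e.hand == cfg.dominant_hand:
            dom_speeds.append(e.peak_speed)
            max_y = max(max_y, e.start_y, e.end_y)
    holds = _raw_still_holds(raw[f_lo:f_hi], spec.fps, cfg)
    return GroundTruth(
        label=label,
        submovements=sub_counts,
        peak_frames=peak_frames,
        holds=holds,
        hold_count=len(holds),
        hold_time_s=float(sum(h.duration_s for h in holds)),
        vertical_amplitude=_amplitude_category(max_y, spec.posture),
        peak_speed_mps=max(dom_speeds),
        distance_m=dist["L"] + dist["R"],
        distance_left_m=dist["L"],
        distance_right_m=dist["R"],
    )


def generate_act(
    spec: ActSpec, cfg: FeatureConfig = FeatureConfig(), label: str = "act"
) -> Tuple[SkeletonSequence, GroundTruth]:
    """Render one act and its ground truth.

    Identical (spec, seed) pairs produce bit-identical recordings.  Jitter
    is applied after the ground truth is computed, so the truth always
    describes the noise-free motion.
    """
    raw, events = _render_raw(spec)
    truth = _truth_for_span(label, events, raw, spec, cfg, 0, spec.n_frames)
    pos = raw
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pos = raw + rng.normal(0.0, spec.jitter_sd, size=raw.shape)
    seq = SkeletonSequence(positions=pos, fps=spec.fps, joints=CANONICAL_JOINTS)
    return seq, truth


# --------------------------------------------------------------------------
# battery construction


#: Hand height (above rest) needed to realize each amplitude category with
#: the default posture, plus a 5 cm margin past the landmark.
_CAT_RISE = {1: 0.10, 2: 0.30, 3: 0.55, 4: 0.77}
#: Base peak speed per category: out-strokes last 18 frames, so reaching
#: higher requires moving faster (D = 0.32 * v for a 0.6 s minimum-jerk
#: stroke); speeds are staggered per act so battery peaks are distinct.
_CAT_BASE_SPEED = {1: 0.50, 2: 1.00, 3: 1.75, 4: 2.45}

_OUT_FRAMES = 18  # 0.6 s at 30 fps: comfortably wider than the smoothing window
_BACK_FRAMES = 23  # return stroke is slower (same amplitude, peak 0.78 * v)


def _battery_spec(
    n_acts: int, fps: float, jitter_sd: float, seed: int, cfg: FeatureConfig
) -> Tuple[ActSpec, List[ActWindow], List[Tuple[int, int]]]:
    """Lay out ``n_acts`` acts on one global timeline.

    Acts cycle through 0-5 dominant-hand submovements, 0-2 holds and the
    four amplitude categories.  Counted strokes alternate out and back
    between the resting hand position and a category-height target; an
    act ending away from rest gets a return stroke in the inter-act
    padding (outside its window) so hands are home before the next act.
    Acts with zero counted submovements contain a slow sub-threshold
    out-and-back instead, so "no submovements" is not just "no motion".
    Stroke durations are fixed at 18/23 frames: long enough for the
    smoothing filter to pass the velocity bell undistorted, short enough
    that millimeter jitter cannot split the bell into two peaks.
    """
    posture = Posture()
    rest_r = posture.rest_hand("R")
    rest_l = posture.rest_hand("L")

    strokes: List[Stroke] = []
    holds: List[Tuple[float, float]] = []
    windows: List[ActWindow] = []
    spans: List[Tuple[int, int]] = []

    def s(frames: int) -> float:
        return frames / fps

    def stroke_to(hand: str, f: int, n_steps: int, target: np.ndarray) -> int:
        strokes.append(Stroke(hand, s(f), s(n_steps), tuple(target)))
        return f + n_steps

    f = int(round(0.5 * fps))  # global cursor, frames
    gap = int(round(0.2 * fps))
    for i in range(n_acts):
        n_sub = i % 6
        n_hold = i % 3
        cat = 1 if n_sub == 0 else (i % 4) + 1
        v_fast = _CAT_BASE_SPEED[cat] + 0.03 * i

        onset_f = f
        f += int(round(0.4 * fps))
        # out-stroke amplitude follows from the fixed 18-frame duration
        amp_out = v_fast * (_OUT_FRAMES / fps) / MINIMUM_JERK_PEAK_FACTOR
        rise = _CAT_RISE[cat]
        lateral = math.sqrt(max(amp_out**2 - rise**2, 1e-6) / 2.0)
        target = rest_r + np.array([lateral, rise, lateral])
        out = True
        for _ in range(n_sub):
            if out:
                f = stroke_to("R", f, _OUT_FRAMES, target)
            else:
                f = stroke_to("R", f, _BACK_FRAMES, rest_r)
            f += gap
            out = not out
        ends_out = not out and n_sub > 0  # last stroke left the hand at the target

        if n_sub == 0:
            # slow sub-threshold out-and-back, peak speed well under 0.2 m/s
            v_slow = 0.06 + 0.002 * i
            n_steps = int(round(1.0 * fps))
            amp = v_slow * (n_steps / fps) / MINIMUM_JERK_PEAK_FACTOR
            slow_t = rest_r + amp * np.array([0.6, 0.6, 0.52915026])  # unit-ish direction
            f = stroke_to("R", f, n_steps, slow_t)
            f += gap
            f = stroke_to("R", f, n_steps, rest_r)
            f += gap

        if i % 3 == 1:
            # a left-hand out-and-back pair exercises the per-hand counts
            v_l = 0.9 + 0.01 * i
            amp_l = v_l * (_OUT_FRAMES / fps) / MINIMUM_JERK_PEAK_FACTOR
            lat_l = math.sqrt(max(amp_l**2 - 0.25**2, 1e-6) / 2.0)
            l_target = rest_l + np.array([-lat_l, 0.25, lat_l])
            f = stroke_to("L", f, _OUT_FRAMES, l_target)
            f += gap
            f = stroke_to("L", f, _BACK_FRAMES, rest_l)
            f += gap

        for h in range(n_hold):
            f += int(round(0.3 * fps))
            dur = int(round((0.4 + 0.1 * h) * fps))
            holds.append((s(f), s(dur)))
            f += dur + int(round(0.3 * fps))

        f += int(round(0.4 * fps))
        offset_f = f
        windows.append(ActWindow(label=f"act{i:03d}", onset_s=s(onset_f), offset_s=s(offset_f)))
        spans.append((onset_f, offset_f))

        # padding: return the right hand to rest outside the window
        if ends_out:
            f += int(round(0.3 * fps))
            f = stroke_to("R", f, _BACK_FRAMES, rest_r)
        f += int(round(0.7 * fps))

    spec = ActSpec(
        duration_s=s(f + int(round(0.5 * fps))),
        fps=fps,
        posture=posture,
        strokes=strokes,
        holds=holds,
        jitter_sd=jitter_sd,
        seed=seed,
    )
    return spec, windows, spans


def generate_dataset(
    n_acts: int = 20,
    seed: int = 0,
    fps: float = 30.0,
    jitter_sd: float = 0.0,
    cfg: FeatureConfig = FeatureConfig(),
    out_dir: Optional[Union[str, Path]] = None,
) -> Tuple[SkeletonSequence, List[ActWindow], pd.DataFrame, List[GroundTruth]]:
    """A reproducible ground-truthed battery of acts in one recording.

    Returns the recording, the act windows, the truth table (one row per
    act) and the per-act :class:`GroundTruth` objects.  Designed act peak
    speeds are pairwise distinct, so dataset-relative quantile binning of
    the battery is well defined.  With ``out_dir`` set, writes
    ``skeleton.csv``, ``windows.csv`` and ``truth.csv`` there.
    """
    if n_acts < 1:
        raise SpecError("n_acts must be >= 1")
    spec, windows, spans = _battery_spec(n_acts, fps, jitter_sd, seed, cfg)
    raw, events = _render_raw(spec)
    truths = [
        _truth_for_span(w.label, events, raw, spec, cfg, lo, hi)
        for w, (lo, hi) in zip(windows, spans)
    ]
    pos = raw
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        pos = raw + rng.normal(0.0, jitter_sd, size=raw.shape)
    seq = SkeletonSequence(positions=pos, fps=fps, joints=CANONICAL_JOINTS)

    truth_df = pd.DataFrame(
        {
            "act_label": [t.label for t in truths],
            "submovements_left": [t.submovements["L"] for t in truths],
            "submovements_right": [t.submovements["R"] for t in truths],
            "submovements_total": [t.submovements["L"] + t.submovements["R"] for t in truths],
            "hold_count": [t.hold_count for t in truths],
            "hold_time_s": [t.hold_time_s for t in truths],
            "vertical_amplitude": [t.vertical_amplitude for t in truths],
            "peak_speed_mps": [t.peak_speed_mps for t in truths],
            "distance_m": [t.distance_m for t in truths],
        }
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_skeleton_table(seq, out_dir / "skeleton.csv")
        write_act_windows(windows, out_dir / "windows.csv")
        truth_df.to_csv(out_dir / "truth.csv", index=False)
    return seq, windows, truth_df, truths
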