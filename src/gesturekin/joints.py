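"""Canonical upper-body joint vocabulary and skeleton topology.

Joint names follow the Kinect V2 convention for the torso, head and arms.
Hips and legs are outside the canonical set: none of the kinematic
features use them.
"""
from __future__ import annotations

from typing import Tuple

#: Midline joints, bottom to top.
CENTRAL_JOINTS: Tuple[str, ...] = (
    "SpineBase",
    "SpineMid",
    "SpineShoulder",
    "Neck",
    "Head",
)

#: Per-side joints, shoulder outward.
SIDED_JOINTS: Tuple[str, ...] = (
    "Shoulder",
    "Elbow",
    "Wrist",
    "Hand",
    "HandTip",
    "Thumb",
)

SIDES: Tuple[str, ...] = ("Left", "Right")

#: The full canonical joint set, in canonical order.
CANONICAL_JOINTS: Tuple[str, ...] = CENTRAL_JOINTS + tuple(
    f"{joint}{side}" for side in SIDES for joint in SIDED_JOINTS
)

#: Joints whose frame-to-frame displacement defines stillness for hold
#: detection: hand, thumb, elbow and shoulder of both arms.
HOLD_JOINTS: Tuple[str, ...] = tuple(
    f"{joint}{side}" for side in SIDES for joint in ("Hand", "Thumb", "Elbow", "Shoulder")
)

#: Body landmarks for the vertical-amplitude categories, bottom to top.
AMPLITUDE_LANDMARKS: Tuple[str, ...] = ("SpineMid", "Neck", "Head")


def hand_joint(side: str) -> str:
    """Return the Hand joint name for ``side`` ('L'/'R' or 'Left'/'Right')."""
    side = {"L": "Left", "R": "Right"}.get(side, side)
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}; expected one of L, R, Left, Right")
    return f"Hand{side}"


#: Stick-figure bone list (pairs of joint names) covering torso, arms and
#: head, the segments drawn in skeleton renders.
BONES: Tuple[Tuple[str, str], ...] = (
    ("SpineBase", "SpineMid"),
    ("SpineMid", "SpineShoulder"),
    ("SpineShoulder", "Neck"),
    ("Neck", "Head"),
    ("SpineShoulder", "ShoulderLeft"),
    ("SpineShoulder", "ShoulderRight"),
    ("ShoulderLeft", "ElbowLeft"),
    ("ElbowLeft", "WristLeft"),
    ("WristLeft", "HandLeft"),
    ("HandLeft", "HandTipLeft"),
    ("HandLeft", "ThumbLeft"),
    ("ShoulderRight", "ElbowRight"),
    ("ElbowRight", "WristRight"),
    ("WristRight", "HandRight"),
    ("HandRight", "HandTipRight"),
    ("HandRight", "ThumbRight"),
)
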