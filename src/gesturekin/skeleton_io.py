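"""Readers and writers for skeleton recordings, act windows and feature tables.

The skeleton dialect is a plain CSV with a ``frame`` column and one
``<Joint>_x``/``_y``/``_z`` column triple per joint, positions in meters.
Axis convention: x lateral, y vertical (positive up), z depth.  Untracked
samples are empty cells and are represented in memory as NaN.

Act windows are a CSV with columns ``label, onset_s, offset_s`` (seconds).
Time convention: frame ``i`` covers ``[i/fps, (i+1)/fps)``; windows are
half-open ``[onset, offset)`` so adjacent windows never share a frame.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .exceptions import SchemaError, TableParseError, WindowValidationError
from .joints import CANONICAL_JOINTS

__all__ = [
    "SkeletonSequence",
    "ActWindow",
    "FEATURE_COLUMNS",
    "read_skeleton_table",
    "write_skeleton_table",
    "read_act_windows",
    "write_act_windows",
    "write_feature_table",
    "read_feature_table",
    "time_to_frame",
]

AXES = ("x", "y", "z")

#: Fixed, ordered header of the per-act feature table.  Auxiliary columns
#: (per-hand distances, per-row error messages) follow these.
FEATURE_COLUMNS: Tuple[str, ...] = (
    "act_label",
    "distance_m",
    "vertical_amplitude",
    "peak_velocity_mps",
    "peak_velocity_bin",
    "submovements_left",
    "submovements_right",
    "submovements_total",
    "hold_count",
    "hold_time_s",
)

AUX_FEATURE_COLUMNS: Tuple[str, ...] = ("distance_left_m", "distance_right_m", "error")


def time_to_frame(t_s: float, fps: float) -> int:
    """Frame index whose interval ``[i/fps, (i+1)/fps)`` contains ``t_s``.

    A small tolerance absorbs binary rounding of products like 0.3 * 30.
    """
    return int(math.floor(t_s * fps + 1e-9))


@dataclass(frozen=True)
class SkeletonSequence:
    """A skeleton recording: frames x joints x 3 positions in meters.

    Parameters
    ----------
    positions : ndarray, shape (n_frames, n_joints, 3)
        Joint positions in meters; NaN marks untracked samples.
    fps : float
        Sampling rate in frames per second, > 0.
    joints : tuple of str
        Joint names in column order (the file header order when read).
    """

    positions: np.ndarray
    fps: float
    joints: Tuple[str, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 3:
            raise ValueError(f"positions must have shape (n_frames, n_joints, 3), got {pos.shape}")
        if pos.shape[1] != len(self.joints):
            raise ValueError(
                f"positions has {pos.shape[1]} joints but {len(self.joints)} names given"
            )
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "joints", tuple(self.joints))

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def joint_index(self) -> Dict[str, int]:
        return {name: i for i, name in enumerate(self.joints)}

    def has_joint(self, joint: str) -> bool:
        return joint in self.joint_index

    def get(self, joint: str) -> np.ndarray:
        """Positions of one joint, shape (n_frames, 3)."""
        try:
            j = self.joint_index[joint]
        except KeyError:
            raise KeyError(
                f"joint {joint!r} not in sequence; available: {', '.join(self.joints)}"
            ) from None
        return self.positions[:, j, :]


@dataclass(frozen=True)
class ActWindow:
    """A labeled half-open time interval [onset_s, offset_s) delimiting one act."""

    label: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise WindowValidationError(
                f"act {self.label!r}: offset ({self.offset_s} s) must exceed onset ({self.onset_s} s)"
            )
        if self.onset_s < 0:
            raise WindowValidationError(f"act {self.label!r}: onset must be nonnegative")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def frame_span(self, fps: float) -> Tuple[int, int]:
        """Half-open frame range [onset_frame, offset_frame)."""
        return time_to_frame(self.onset_s, fps), time_to_frame(self.offset_s, fps)


def _joint_columns(joint: str) -> List[str]:
    return [f"{joint}_{ax}" for ax in AXES]


def read_skeleton_table(
    path: Union[str, Path],
    fps: float,
    required_joints: Optional[Sequence[str]] = None,
    sep: str = ",",
) -> SkeletonSequence:
    """Read a skeleton CSV into a :class:`SkeletonSequence`.

    Every ``<Joint>_x/_y/_z`` column triple found in the header becomes a
    joint, in header order.  ``required_joints`` (default: the canonical
    set) must all be present; empty cells become NaN (untracked), and any
    other non-numeric cell raises :class:`TableParseError` with its file
    line number.
    """
    if required_joints is None:
        required_joints = CANONICAL_JOINTS
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    header = list(raw.columns)

    # joints appear in file order of their _x column
    joints = [c[:-2] for c in header if c.endswith("_x")]
    missing = sorted(
        {j for j in required_joints if any(f"{j}_{ax}" not in header for ax in AXES)}
    )
    if missing:
        raise SchemaError(
            f"{path.name}: missing position columns for joints: {', '.join(missing)}"
        )
    incomplete = [j for j in joints if any(f"{j}_{ax}" not in header for ax in AXES)]
    if incomplete:
        raise SchemaError(
            f"{path.name}: incomplete x/y/z column triples for joints: {', '.join(incomplete)}"
        )

    n = len(raw)
    pos = np.full((n, len(joints), 3), np.nan)
    for ji, joint in enumerate(joints):
        for ai, ax in enumerate(AXES):
            col = raw[f"{joint}_{ax}"]
            vals = pd.to_numeric(col, errors="coerce")
            bad = vals.isna() & col.notna() & (col.str.strip() != "")
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise TableParseError(
                    f"{path.name}, line {row + 2}, column {joint}_{ax}: "
                    f"non-numeric value {col.iloc[row]!r}"
                )
            pos[:, ji, ai] = vals.to_numpy()
    return SkeletonSequence(positions=pos, fps=fps, joints=tuple(joints))


def write_skeleton_table(seq: SkeletonSequence, path: Union[str, Path], sep: str = ",") -> None:
    """Write a skeleton CSV in the dialect :func:`read_skeleton_table` reads.

    Values are written at full float precision so that a write/read round
    trip reproduces positions exactly; NaN becomes an empty cell.
    """
    data: Dict[str, np.ndarray] = {"frame": np.arange(seq.n_frames)}
    for ji, joint in enumerate(seq.joints):
        for ai, ax in enumerate(AXES):
            data[f"{joint}_{ax}"] = seq.positions[:, ji, ai]
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, na_rep="")


def read_act_windows(path: Union[str, Path], sep: str = ",") -> List[ActWindow]:
    """Read, sort by onset and validate an act-window CSV (label,onset_s,offset_s)."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, skipinitialspace=True)
    needed = {"label", "onset_s", "offset_s"}
    if not needed.issubset(df.columns):
        raise SchemaError(
            f"{path.name}: act-window file needs columns label, onset_s, offset_s; "
            f"found {', '.join(df.columns)}"
        )
    windows = [
        ActWindow(label=str(r.label), onset_s=float(r.onset_s), offset_s=float(r.offset_s))
        for r in df.itertuples()
    ]
    windows.sort(key=lambda w: (w.onset_s, w.offset_s))
    for prev, cur in zip(windows, windows[1:]):
        if cur.onset_s < prev.offset_s - 1e-12:
            raise WindowValidationError(
                f"acts {prev.label!r} and {cur.label!r} overlap "
                f"([{prev.onset_s}, {prev.offset_s}) vs [{cur.onset_s}, {cur.offset_s}))"
            )
    return windows


def write_act_windows(windows: Sequence[ActWindow], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "label": [w.label for w in windows],
            "onset_s": [w.onset_s for w in windows],
            "offset_s": [w.offset_s for w in windows],
        }
    ).to_csv(path, index=False)


def write_feature_table(table, path: Union[str, Path]) -> None:
    """Write a feature table CSV with the fixed column order.

    ``table`` is a :class:`~gesturekin.features.FeatureTable` or a
    DataFrame already containing the fixed columns.  An empty table is an
    error and nothing is written.
    """
    df = table.to_dataframe() if hasattr(table, "to_dataframe") else pd.DataFrame(table)
    if len(df) == 0:
        raise ValueError("refusing to write an empty feature table")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns: {', '.join(missing)}")
    aux = [c for c in AUX_FEATURE_COLUMNS if c in df.columns]
    df = df[list(FEATURE_COLUMNS) + aux]
    df.to_csv(path, index=False, na_rep="")


def read_feature_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a feature-table CSV (ours or a manual-coding export sharing the header)."""
    df = pd.read_csv(Path(path))
    if "act_label" not in df.columns:
        raise SchemaError(f"{Path(path).name}: feature table needs an act_label column")
    return df
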