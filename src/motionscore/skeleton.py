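"""Skeleton joint schema and motion file I/O.

A motion is an ordered sequence of frames, each giving the 3D world
position (meters, right-handed, y-up) of 12 limb joints — the shoulders,
elbows, wrists, hips, knees and ankles of both sides.  These define the
eight major limb bones (upper/lower arm, upper/lower leg, left/right)
used for pose comparison.

Two on-disk dialects are supported:

* **CSV** — header ``time,ShoulderLeft_x,ShoulderLeft_y,ShoulderLeft_z,…``
  with the 12 joints in the fixed order of :data:`JOINT_NAMES`, one row
  per frame.
* **JSON-lines** — one object per line:
  ``{"t": <sec>, "joints": {"ShoulderLeft": [x, y, z], …}}``.

Frames missing any required joint (or holding non-finite values) are
dropped with a logged count rather than interpolated; downstream dynamic
time warping absorbs the resulting timing gaps.  Unknown extra joints
(``Head``, ``SpineBase``, …) are ignored with a warning so that raw
Kinect exports load without preprocessing.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    EmptySequence,
    IOFailure,
    MissingColumn,
    NonMonotonicTime,
)

logger = logging.getLogger(__name__)

#: The 12 required joints, in canonical column order.
JOINT_NAMES: tuple[str, ...] = (
    "ShoulderLeft",
    "ElbowLeft",
    "WristLeft",
    "ShoulderRight",
    "ElbowRight",
    "WristRight",
    "HipLeft",
    "KneeLeft",
    "AnkleLeft",
    "HipRight",
    "KneeRight",
    "AnkleRight",
)

#: The eight limb bones as (name, proximal joint, distal joint), in the
#: fixed feature order used throughout the package.
BONES: tuple[tuple[str, str, str], ...] = (
    ("UpperArmLeft", "ShoulderLeft", "ElbowLeft"),
    ("LowerArmLeft", "ElbowLeft", "WristLeft"),
    ("UpperArmRight", "ShoulderRight", "ElbowRight"),
    ("LowerArmRight", "ElbowRight", "WristRight"),
    ("UpperLegLeft", "HipLeft", "KneeLeft"),
    ("LowerLegLeft", "KneeLeft", "AnkleLeft"),
    ("UpperLegRight", "HipRight", "KneeRight"),
    ("LowerLegRight", "KneeRight", "AnkleRight"),
)

#: Minimum admissible bone length in meters.
MIN_BONE_LENGTH = 1e-6


@dataclass
class SkeletonFrame:
    """One time-stamped skeleton pose.

    Parameters
    ----------
    timestamp : float
        Seconds since the start of the recording; strictly increasing
        within a sequence.
    positions : dict
        Mapping of joint name to a length-3 float array in meters
        (world frame, y up).
    """

    timestamp: float
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.positions = {
            name: np.asarray(p, dtype=float) for name, p in self.positions.items()
        }

    def has_all_joints(self) -> bool:
        return all(
            j in self.positions and np.all(np.isfinite(self.positions[j]))
            for j in JOINT_NAMES
        )


@dataclass
class MotionSequence:
    """An ordered list of skeleton frames plus bookkeeping metadata."""

    frames: list[SkeletonFrame]
    frame_rate: float = 30.0
    label: str = ""
    dropped_frames: int = 0

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])

    def positions_array(self) -> np.ndarray:
        """Stack positions into an ``(n_frames, 12, 3)`` array in
        :data:`JOINT_NAMES` order."""
        return np.array(
            [[f.positions[j] for j in JOINT_NAMES] for f in self.frames]
        )


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("csv", "jsonl"):
            raise IOFailure(f"unknown format {format!r}; expected 'csv' or 'jsonl'")
        return format
    return "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson", ".json") else "csv"


def _infer_rate(timestamps: np.ndarray) -> float:
    if len(timestamps) < 2:
        return 30.0
    dt = float(np.median(np.diff(timestamps)))
    return 1.0 / dt if dt > 0 else 30.0


def _check_monotonic(timestamps: Iterable[float]) -> None:
    ts = np.asarray(list(timestamps), dtype=float)
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        bad = int(np.flatnonzero(np.diff(ts) <= 0)[0]) + 1
        raise NonMonotonicTime(f"timestamps not strictly increasing at frame {bad}")


def read_motion(path: str | Path, format: str | None = None) -> MotionSequence:
    """Read a motion sequence from a CSV or JSON-lines file.

    Frames with missing or non-finite joint values are dropped (the
    count is logged and recorded on the returned sequence).

    Raises
    ------
    MissingColumn
        A required ``<Joint>_<axis>`` column is absent from a CSV header.
    EmptySequence
        No valid frame remains after filtering.
    NonMonotonicTime
        Timestamps of the kept frames are not strictly increasing.
    """
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "csv":
        seq = _read_csv(path)
    else:
        seq = _read_jsonl(path)
    if not seq.frames:
        raise EmptySequence(f"{path}: no valid frames")
    _check_monotonic(f.timestamp for f in seq.frames)
    if seq.dropped_frames:
        logger.warning(
            "%s: dropped %d frame(s) with missing/non-finite joints",
            path,
            seq.dropped_frames,
        )
    return seq


def _read_csv(path: Path) -> MotionSequence:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise IOFailure(f"{path}: {exc}") from exc
    if "time" not in df.columns:
        raise MissingColumn(f"{path}: missing required column 'time'")
    required = [f"{j}_{ax}" for j in JOINT_NAMES for ax in "xyz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumn(f"{path}: missing required column(s) {missing[:3]}")
    known = {"time", *required}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("%s: ignoring %d unknown column(s): %s", path, len(extra), extra[:5])

    frames: list[SkeletonFrame] = []
    dropped = 0
    values = df[required].to_numpy(dtype=float).reshape(len(df), len(JOINT_NAMES), 3)
    times = df["time"].to_numpy(dtype=float)
    for t, row in zip(times, values):
        if not (np.all(np.isfinite(row)) and math.isfinite(t)):
            dropped += 1
            continue
        frames.append(
            SkeletonFrame(t, dict(zip(JOINT_NAMES, row)))
        )
    return MotionSequence(
        frames,
        frame_rate=_infer_rate(np.array([f.timestamp for f in frames])),
        label=path.stem,
        dropped_frames=dropped,
    )


def _read_jsonl(path: Path) -> MotionSequence:
    frames: list[SkeletonFrame] = []
    dropped = 0
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise IOFailure(f"{path}: {exc}") from exc
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            t = float(obj["t"])
            joints: Mapping[str, list[float]] = obj["joints"]
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise IOFailure(f"{path}:{lineno}: malformed record ({exc})") from exc
        unknown = set(joints) - set(JOINT_NAMES)
        if unknown:
            logger.warning("%s:%d: ignoring unknown joint(s) %s", path, lineno, sorted(unknown)[:5])
        positions = {}
        ok = math.isfinite(t)
        for j in JOINT_NAMES:
            if j not in joints:
                ok = False
                break
            p = np.asarray(joints[j], dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                ok = False
                break
            positions[j] = p
        if not ok:
            dropped += 1
            continue
        frames.append(SkeletonFrame(t, positions))
    return MotionSequence(
        frames,
        frame_rate=_infer_rate(np.array([f.timestamp for f in frames])),
        label=path.stem,
        dropped_frames=dropped,
    )


def write_motion(seq: MotionSequence, path: str | Path, format: str | None = None) -> None:
    """Write a motion sequence to CSV or JSON-lines with full float
    precision, so that a read/write round trip reproduces positions to
    better than 1e-9 m."""
    if not seq.frames:
        raise EmptySequence("cannot write an empty sequence")
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "csv":
            header = ["time"] + [f"{j}_{ax}" for j in JOINT_NAMES for ax in "xyz"]
            with open(path, "w", newline="") as fh:
                fh.write(",".join(header) + "\n")
                for f in seq.frames:
                    row = [repr(float(f.timestamp))]
                    for j in JOINT_NAMES:
                        row.extend(repr(float(v)) for v in f.positions[j])
                    fh.write(",".join(row) + "\n")
        else:
            with open(path, "w") as fh:
                for f in seq.frames:
                    obj = {
                        "t": float(f.timestamp),
                        "joints": {j: [float(v) for v in f.positions[j]] for j in JOINT_NAMES},
                    }
                    fh.write(json.dumps(obj) + "\n")
    except OSError as exc:
        raise IOFailure(f"{path}: {exc}") from exc


@dataclass
class Issue:
    """One machine-readable validation finding."""

    frame: int
    kind: str
    joint: str = ""
    detail: str = ""


def validate_sequence(seq: MotionSequence) -> list[Issue]:
    """Check every sequence invariant and report violations.

    Returns an empty list iff the sequence is valid: at least one frame,
    strictly increasing timestamps, all 12 joints present and finite in
    every frame, and every bone longer than :data:`MIN_BONE_LENGTH`.
    """
    issues: list[Issue] = []
    if not seq.frames:
        return [Issue(frame=-1, kind="EmptySequence")]
    prev_t = -math.inf
    for i, f in enumerate(seq.frames):
        if f.timestamp <= prev_t:
            issues.append(Issue(frame=i, kind="NonMonotonicTime",
                                detail=f"t={f.timestamp} after t={prev_t}"))
        prev_t = f.timestamp
        for j in JOINT_NAMES:
            if j not in f.positions:
                issues.append(Issue(frame=i, kind="MissingJoint", joint=j))
            elif not np.all(np.isfinite(f.positions[j])):
                issues.append(Issue(frame=i, kind="NonFiniteValue", joint=j))
        for name, parent, child in BONES:
            if parent in f.positions and child in f.positions:
                length = float(np.linalg.norm(f.positions[child] - f.positions[parent]))
                if length <= MIN_BONE_LENGTH and np.all(
                    np.isfinite(f.positions[child])
                ) and np.all(np.isfinite(f.positions[parent])):
                    issues.append(
                        Issue(frame=i, kind="DegenerateBone", joint=name,
                              detail=f"length {length:.2e} m")
                    )
    return issues
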