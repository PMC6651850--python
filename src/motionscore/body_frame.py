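"""Per-frame local body coordinate system and pose features.

Comparing bone vectors in world coordinates penalizes a trainee who
performs a motion perfectly but faces a different direction than the
reference: the heading error leaks into all eight bones.  The fix is a
local, body-attached coordinate frame rebuilt independently at every
frame from the subject's own limb geometry:

* **up** — direction from the midpoint of the two upper-leg segments to
  the midpoint of the two upper-arm segments, then snapped to the world
  ground normal ``(0, 1, 0)``;
* **left** — average of the upper-body left direction (left upper-arm
  midpoint minus right upper-arm midpoint) and the lower-body left
  direction (same for the upper legs);
* **forward** — ``up x left`` (right-handed), projected into the ground
  plane so the x- and z-axes always lie on the ground.

Expressed in this basis, the eight bone vectors are invariant to any
whole-body rotation about the vertical axis and to translation.  The
heading itself is kept as a ninth feature: the world-frame forward
vector, whose angular difference between two skeletons measures trunk
orientation mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateBone,
    DegenerateFrame,
    EmptySequence,
    ZeroVector,
)
from .skeleton import BONES, MIN_BONE_LENGTH, MotionSequence, SkeletonFrame

logger = logging.getLogger(__name__)

WORLD_UP = np.array([0.0, 1.0, 0.0])

#: Number of bone feature dimensions (excludes the forward vector).
N_BONES = len(BONES)


def _normalize(v: np.ndarray, err: type[Exception], what: str, tol: float = 1e-12) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n <= tol:
        raise err(f"{what}: zero-length vector")
    return v / n


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180].

    Computed as the arccosine of the normalized dot product (law of
    cosines on the triangle spanned by the two unit vectors), clipped
    against rounding.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu <= 1e-12 or nv <= 1e-12:
        raise ZeroVector("angle_between requires non-zero vectors")
    c = float(np.dot(u, v)) / (nu * nv)
    # snap numerically (anti)parallel vectors to exact endpoints; arccos
    # turns last-ulp noise near +-1 into phantom microdegree angles
    if c >= 1.0 - 1e-12:
        return 0.0
    if c <= -1.0 + 1e-12:
        return 180.0
    return float(np.degrees(np.arccos(c)))


def bone_vector(frame: SkeletonFrame, parent: str, child: str) -> np.ndarray:
    """Unit vector from the proximal to the distal joint, world frame."""
    d = frame.positions[child] - frame.positions[parent]
    n = float(np.linalg.norm(d))
    if n <= MIN_BONE_LENGTH:
        raise DegenerateBone(f"{parent}->{child}: bone length {n:.2e} m")
    return d / n


@dataclass
class BodyBasis:
    """Orthonormal body-attached frame with up pinned to the world
    ground normal; ``left`` and ``forward`` lie in the ground plane."""

    origin: np.ndarray
    left: np.ndarray
    up: np.ndarray
    forward: np.ndarray

    def rotation(self) -> np.ndarray:
        """World-to-local rotation matrix (rows = basis axes)."""
        return np.stack([self.left, self.up, self.forward])


def _midpoint(frame: SkeletonFrame, a: str, b: str) -> np.ndarray:
    return 0.5 * (frame.positions[a] + frame.positions[b])


def build_body_basis(frame: SkeletonFrame) -> BodyBasis:
    """Construct the local body coordinate system for one frame.

    Raises
    ------
    DegenerateFrame
        The provisional up and left directions are (anti)parallel, or
        the body axis is so close to horizontal that the forward vector
        has no ground-plane component.
    """
    m_ua_l = _midpoint(frame, "ShoulderLeft", "ElbowLeft")
    m_ua_r = _midpoint(frame, "ShoulderRight", "ElbowRight")
    m_ul_l = _midpoint(frame, "HipLeft", "KneeLeft")
    m_ul_r = _midpoint(frame, "HipRight", "KneeRight")

    up0 = _normalize(
        0.5 * (m_ua_l + m_ua_r) - 0.5 * (m_ul_l + m_ul_r), DegenerateFrame, "up axis"
    )
    left0 = _normalize(
        _normalize(m_ua_l - m_ua_r, DegenerateFrame, "upper-body left")
        + _normalize(m_ul_l - m_ul_r, DegenerateFrame, "lower-body left"),
        DegenerateFrame,
        "left axis",
    )
    cross = np.cross(up0, left0)
    # |up0 x left0| = sin(angle); reject angles outside (1, 179) degrees
    if float(np.linalg.norm(cross)) < np.sin(np.radians(1.0)):
        raise DegenerateFrame("up and left axes are (anti)parallel")
    forward0 = cross / np.linalg.norm(cross)

    # Ground alignment: pin up to the world normal, project forward into
    # the ground plane, rebuild left to restore orthonormality.
    fw = forward0 * np.array([1.0, 0.0, 1.0])
    n = float(np.linalg.norm(fw))
    if n < 1e-6:
        raise DegenerateFrame("forward axis nearly vertical; no ground projection")
    forward = fw / n
    up = WORLD_UP.copy()
    left = np.cross(up, forward)

    origin = _midpoint(frame, "HipLeft", "HipRight") * np.array([1.0, 0.0, 1.0])
    return BodyBasis(origin=origin, left=left, up=up, forward=forward)


def to_local(v: np.ndarray, basis: BodyBasis) -> np.ndarray:
    """Express a world-frame vector in the body basis.

    Rotation only — bone vectors are differences of positions and hence
    translation-invariant; the basis origin is irrelevant here.
    """
    return basis.rotation() @ np.asarray(v, dtype=float)


@dataclass
class FeatureFrame:
    """The 9-dimensional pose descriptor of one frame.

    ``bones`` is an ``(8, 3)`` array of unit bone vectors in the fixed
    order of :data:`motionscore.skeleton.BONES`, expressed either in the
    local body basis (default pipeline) or in world coordinates (the
    ablation mode); ``forward`` is the world-frame body heading.
    """

    bones: np.ndarray
    forward: np.ndarray


@dataclass
class FeatureSequence:
    """Stacked pose features for a whole motion.

    Attributes
    ----------
    bones : ndarray, shape (n, 8, 3)
    forward : ndarray, shape (n, 3)
    label : str
    frame_kind : {"local", "world"}
        Coordinate system the bone vectors are expressed in.
    dropped_frames : int
        Frames discarded because no body basis could be built.
    """

    bones: np.ndarray
    forward: np.ndarray
    label: str = ""
    frame_kind: str = "local"
    dropped_frames: int = 0

    def __len__(self) -> int:
        return self.bones.shape[0]

    def __getitem__(self, i: int) -> FeatureFrame:
        return FeatureFrame(bones=self.bones[i], forward=self.forward[i])


def extract_features(seq: MotionSequence, frame_kind: str = "local") -> FeatureSequence:
    """Convert a motion sequence into per-frame 9-vector pose features.

    Parameters
    ----------
    seq : MotionSequence
    frame_kind : {"local", "world"}
        ``"local"`` expresses bone vectors in the per-frame body basis
        (orientation-invariant); ``"world"`` keeps them in world
        coordinates, which exposes heading errors in every bone and is
        provided for comparison.

    Frames whose geometry does not admit a body basis are dropped with a
    logged count.
    """
    if frame_kind not in ("local", "world"):
        raise ValueError(f"frame_kind must be 'local' or 'world', got {frame_kind!r}")
    if not seq.frames:
        raise EmptySequence("cannot extract features from an empty sequence")
    bones_out = []
    forward_out = []
    dropped = 0
    for f in seq.frames:
        try:
            basis = build_body_basis(f)
            world_bones = np.stack(
                [bone_vector(f, parent, child) for _, parent, child in BONES]
            )
        except (DegenerateFrame, DegenerateBone, KeyError):
            dropped += 1
            continue
        if frame_kind == "local":
            bones_out.append(world_bones @ basis.rotation().T)
        else:
            bones_out.append(world_bones)
        forward_out.append(basis.forward)
    if not bones_out:
        raise EmptySequence("all frames degenerate; no features extracted")
    if dropped:
        logger.warning("%s: dropped %d degenerate frame(s)", seq.label, dropped)
    return FeatureSequence(
        bones=np.stack(bones_out),
        forward=np.stack(forward_out),
        label=seq.label,
        frame_kind=frame_kind,
        dropped_frames=dropped,
    )
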