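import numpy as np
import pytest

from motionscore.body_frame import FeatureSequence
from motionscore.skeleton import JOINT_NAMES, MotionSequence, SkeletonFrame


def t_pose_frame(t: float = 0.0) -> SkeletonFrame:
    """Upright T-pose: shoulders along +-x, arms straight out, legs
    straight down, provisional facing along -z under the package's
    sign convention."""
    pos = {
        "ShoulderLeft": [0.175, 1.5, 0.0],
        "ElbowLeft": [0.475, 1.5, 0.0],
        "WristLeft": [0.745, 1.5, 0.0],
        "ShoulderRight": [-0.175, 1.5, 0.0],
        "ElbowRight": [-0.475, 1.5, 0.0],
        "WristRight": [-0.745, 1.5, 0.0],
        "HipLeft": [0.15, 1.0, 0.0],
        "KneeLeft": [0.15, 0.55, 0.0],
        "AnkleLeft": [0.15, 0.13, 0.0],
        "HipRight": [-0.15, 1.0, 0.0],
        "KneeRight": [-0.15, 0.55, 0.0],
        "AnkleRight": [-0.15, 0.13, 0.0],
    }
    return SkeletonFrame(t, {k: np.array(v) for k, v in pos.items()})


@pytest.fixture
def t_pose() -> SkeletonFrame:
    return t_pose_frame()


@pytest.fixture
def t_pose_sequence() -> MotionSequence:
    return MotionSequence([t_pose_frame(i / 30.0) for i in range(5)], frame_rate=30.0)


def random_unit_vectors(rng: np.random.Generator, shape) -> np.ndarray:
    v = rng.normal(size=shape + (3,))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def random_feature_sequence(rng: np.random.Generator, n: int) -> FeatureSequence:
    """Random 9-dim features: 8 random unit bone vectors per frame plus
    a random ground-plane forward vector."""
    bones = random_unit_vectors(rng, (n, 8))
    azimuth = rng.uniform(0, 2 * np.pi, size=n)
    forward = np.stack([np.sin(azimuth), np.zeros(n), np.cos(azimuth)], axis=1)
    return FeatureSequence(bones=bones, forward=forward, label="random")


def rotate_sequence_y(seq: MotionSequence, degrees: float) -> MotionSequence:
    """Rigidly rotate every joint about the world vertical axis."""
    phi = np.radians(degrees)
    c, s = np.cos(phi), np.sin(phi)
    rot = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    frames = [
        SkeletonFrame(f.timestamp, {j: rot @ f.positions[j] for j in JOINT_NAMES})
        for f in seq.frames
    ]
    return MotionSequence(frames, frame_rate=seq.frame_rate, label=seq.label)


def translate_sequence(seq: MotionSequence, offset) -> MotionSequence:
    offset = np.asarray(offset, dtype=float)
    frames = [
        SkeletonFrame(f.timestamp, {j: f.positions[j] + offset for j in JOINT_NAMES})
        for f in seq.frames
    ]
    return MotionSequence(frames, frame_rate=seq.frame_rate, label=seq.label)
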