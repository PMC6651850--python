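"""Training-free scoring of skeleton exercise motion against a reference.

Given two skeleton joint-position time series — a reference performance
(virtual coach) and a test performance (trainee) — the package extracts
a 9-dimensional unit-vector pose descriptor per frame (eight limb bone
vectors in a body-attached, heading-invariant coordinate frame, plus
the body's forward vector), aligns the two sequences by
multi-dimensional dynamic time warping under a summed-angle cost, and
converts the cumulative distance into a 0-100% performance score with
no training data.  Utilities for calibrating raw scores to expert
ratings and for reliability statistics (Pearson r, ICC(2,k)) round out
the validation workflow.
"""

from __future__ import annotations

from .body_frame import (
    BodyBasis,
    FeatureFrame,
    FeatureSequence,
    angle_between,
    bone_vector,
    build_body_basis,
    extract_features,
    to_local,
)
from .dtw import (
    AlignmentResult,
    WarpingPath,
    brute_force_align,
    cost_matrix,
    dtw_align,
    frame_by_frame_align,
    frame_cost,
)
from .scoring import (
    CalibrationModel,
    PerformanceScore,
    apply_calibration,
    fit_calibration,
    icc,
    pearson_r,
    performance_score,
    read_ratings,
)
from .skeleton import (
    BONES,
    JOINT_NAMES,
    MotionSequence,
    SkeletonFrame,
    read_motion,
    validate_sequence,
    write_motion,
)
from .synthetic import (
    PerturbationSpec,
    SkeletonTemplate,
    SyntheticPair,
    generate_base_motion,
    make_pair,
    perturb,
)

__version__ = "0.1.0"


def score_motions(
    reference: MotionSequence,
    test: MotionSequence,
    dims: int = 9,
    max_angle: float = 90.0,
    frame_kind: str = "local",
) -> tuple[PerformanceScore, AlignmentResult]:
    """End-to-end scoring: features, DTW alignment, percentage score.

    Returns the score together with the alignment it was derived from.
    """
    feats_ref = extract_features(reference, frame_kind=frame_kind)
    feats_test = extract_features(test, frame_kind=frame_kind)
    alignment = dtw_align(feats_ref, feats_test, dims=dims, max_angle=max_angle)
    return performance_score(alignment), alignment
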