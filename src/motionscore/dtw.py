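"""Multi-dimensional dynamic time warping over pose features.

The frame-pair cost is the sum, over feature dimensions, of the angular
difference (degrees) between corresponding unit vectors, each clamped at
``max_angle`` (default 90 deg).  The clamp encodes the modeling
assumption that corresponding bones of two people doing the same
exercise stay within a quarter turn of each other; it also bounds the
cost per matched pair by ``max_angle * dims``, which is what lets the
cumulative distance be converted to a percentage score downstream.

``dtw_align`` runs the classic O(n*m) dynamic program (steps down,
right, diagonal; no slope or band constraint by default) and backtracks
the optimal warping path, breaking ties diagonal > vertical >
horizontal.  ``brute_force_align`` enumerates every admissible warping
path and is the test oracle for small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body_frame import FeatureFrame, FeatureSequence, N_BONES, angle_between
from .errors import DimensionMismatch, EmptySequence, TooLarge

DEFAULT_MAX_ANGLE = 90.0
DEFAULT_DIMS = 9


def _check_dims(dims: int, max_angle: float) -> None:
    if dims not in (8, 9):
        raise DimensionMismatch(f"dims must be 8 or 9, got {dims}")
    if not 0.0 < max_angle <= 180.0:
        raise ValueError(f"max_angle must be in (0, 180], got {max_angle}")


def frame_cost(
    a: FeatureFrame,
    b: FeatureFrame,
    dims: int = DEFAULT_DIMS,
    max_angle: float = DEFAULT_MAX_ANGLE,
) -> float:
    """Summed clamped angle difference between two pose frames, degrees.

    With ``dims=9`` the body-heading (forward vector) difference is
    included as the ninth term; with ``dims=8`` only the bones count.
    """
    _check_dims(dims, max_angle)
    if a.bones.shape != (N_BONES, 3) or b.bones.shape != (N_BONES, 3):
        raise DimensionMismatch(
            f"expected ({N_BONES}, 3) bone arrays, got {a.bones.shape} and {b.bones.shape}"
        )
    total = sum(
        min(angle_between(a.bones[k], b.bones[k]), max_angle) for k in range(N_BONES)
    )
    if dims == 9:
        total += min(angle_between(a.forward, b.forward), max_angle)
    return float(total)


#: Dot products within this distance of +-1 are snapped to exactly
#: 0 / 180 degrees: arccos near its endpoints amplifies last-ulp noise
#: into ~1e-6-degree phantom angles, which would otherwise accumulate
#: over thousands of matched pairs and keep identical motions from
#: scoring an exact 100%.
_PARALLEL_TOL = 1e-12


def _pairwise_angles(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Angles (degrees) between every row of A (n,3) and of B (m,3)."""
    dots = A @ B.T
    ang = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    ang[dots >= 1.0 - _PARALLEL_TOL] = 0.0
    ang[dots <= -1.0 + _PARALLEL_TOL] = 180.0
    return ang


def cost_matrix(
    S: FeatureSequence,
    T: FeatureSequence,
    dims: int = DEFAULT_DIMS,
    max_angle: float = DEFAULT_MAX_ANGLE,
) -> np.ndarray:
    """Dense n-by-m matrix of frame-pair costs (degrees)."""
    _check_dims(dims, max_angle)
    if len(S) == 0 or len(T) == 0:
        raise EmptySequence("cost_matrix requires non-empty sequences")
    C = np.zeros((len(S), len(T)))
    for k in range(N_BONES):
        C += np.minimum(_pairwise_angles(S.bones[:, k, :], T.bones[:, k, :]), max_angle)
    if dims == 9:
        C += np.minimum(_pairwise_angles(S.forward, T.forward), max_angle)
    return C


@dataclass
class WarpingPath:
    """Monotone alignment between two sequences, 1-based index pairs."""

    pairs: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def s(self) -> int:
        """Path length (number of matched frame pairs)."""
        return len(self.pairs)

    def is_valid(self, n: int, m: int) -> bool:
        """Boundary, monotonicity and unit-step conditions."""
        if not self.pairs or self.pairs[0] != (1, 1) or self.pairs[-1] != (n, m):
            return False
        steps = {(1, 0), (0, 1), (1, 1)}
        return all(
            (b[0] - a[0], b[1] - a[1]) in steps
            for a, b in zip(self.pairs, self.pairs[1:])
        )


@dataclass
class AlignmentResult:
    """Outcome of a DTW alignment.

    ``distance`` is the cumulative cost (degrees) of the optimal warping
    path; ``accumulated`` is the full dynamic-programming matrix D (or
    None for alignments that do not build one).  ``dims`` and
    ``max_angle`` record the cost configuration so that scoring can
    verify consistency.
    """

    distance: float
    path: WarpingPath
    accumulated: np.ndarray | None = None
    dims: int = DEFAULT_DIMS
    max_angle: float = DEFAULT_MAX_ANGLE

    @property
    def s(self) -> int:
        return self.path.s


def _accumulate(C: np.ndarray) -> np.ndarray:
    """Fill the DP matrix D(i,j) = C(i,j) + min of the three
    predecessors, sweeping anti-diagonals so each sweep is vectorized."""
    n, m = C.shape
    D = np.empty_like(C)
    D[0, :] = np.cumsum(C[0, :])
    D[:, 0] = np.cumsum(C[:, 0])
    for d in range(2, n + m - 1):
        lo = max(1, d - (m - 1))
        hi = min(n - 1, d - 1)
        if hi < lo:
            continue
        i = np.arange(lo, hi + 1)
        j = d - i
        best = np.minimum(D[i - 1, j - 1], np.minimum(D[i - 1, j], D[i, j - 1]))
        D[i, j] = best + C[i, j]
    return D


def _backtrack(D: np.ndarray) -> WarpingPath:
    """Walk the DP matrix from (n,m) back to (1,1), preferring
    diagonal, then vertical, then horizontal on ties."""
    i, j = D.shape[0] - 1, D.shape[1] - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            candidates = (
                (D[i - 1, j - 1], i - 1, j - 1),
                (D[i - 1, j], i - 1, j),
                (D[i, j - 1], i, j - 1),
            )
            best = min(c[0] for c in candidates)
            for val, pi, pj in candidates:
                if val == best:
                    i, j = pi, pj
                    break
        rev.append((i, j))
    return WarpingPath([(a + 1, b + 1) for a, b in reversed(rev)])


def dtw_align(
    S: FeatureSequence,
    T: FeatureSequence,
    dims: int = DEFAULT_DIMS,
    max_angle: float = DEFAULT_MAX_ANGLE,
    band: int | None = None,
) -> AlignmentResult:
    """Optimal DTW alignment of two feature sequences.

    Parameters
    ----------
    S, T : FeatureSequence
        Reference and test features (order does not affect the distance).
    dims : {8, 9}
        8 = bones only; 9 = bones plus body heading.
    max_angle : float
        Per-dimension clamp in degrees.
    band : int, optional
        Sakoe–Chiba band half-width in frames; cells with |i - j| beyond
        it are excluded.  Default None (unconstrained).
    """
    C = cost_matrix(S, T, dims=dims, max_angle=max_angle)
    if band is not None:
        n, m = C.shape
        ii, jj = np.indices((n, m))
        C = np.where(np.abs(ii - jj) <= band, C, np.inf)
    D = _accumulate(C)
    path = _backtrack(D)
    return AlignmentResult(
        distance=float(D[-1, -1]), path=path, accumulated=D,
        dims=dims, max_angle=max_angle,
    )


def frame_by_frame_align(
    S: FeatureSequence,
    T: FeatureSequence,
    dims: int = DEFAULT_DIMS,
    max_angle: float = DEFAULT_MAX_ANGLE,
) -> AlignmentResult:
    """Naive comparison without time warping: frame i matches frame i.

    The path runs down the diagonal and, if lengths differ, along the
    final row/column.  Serves as the no-DTW baseline showing what time
    distortion costs a rigid comparison.
    """
    n, m = len(S), len(T)
    if n == 0 or m == 0:
        raise EmptySequence("frame_by_frame_align requires non-empty sequences")
    C = cost_matrix(S, T, dims=dims, max_angle=max_angle)
    pairs = [(i, i) for i in range(min(n, m))]
    if n > m:
        pairs += [(i, m - 1) for i in range(m, n)]
    elif m > n:
        pairs += [(n - 1, j) for j in range(n, m)]
    dist = float(sum(C[i, j] for i, j in pairs))
    return AlignmentResult(
        distance=dist,
        path=WarpingPath([(i + 1, j + 1) for i, j in pairs]),
        accumulated=None,
        dims=dims,
        max_angle=max_angle,
    )


MAX_BRUTE_FORCE = 8


def brute_force_align(
    S: FeatureSequence,
    T: FeatureSequence,
    dims: int = DEFAULT_DIMS,
    max_angle: float = DEFAULT_MAX_ANGLE,
) -> AlignmentResult:
    """Exhaustively enumerate every admissible warping path.

    The independent oracle for :func:`dtw_align`: returns the minimum
    total cost over all paths and, among minimizers, the path the
    dynamic program's diagonal-first backtracking would choose.  Path
    counts grow as Delannoy numbers, so inputs are capped at
    ``MAX_BRUTE_FORCE`` frames per side.
    """
    n, m = len(S), len(T)
    if n == 0 or m == 0:
        raise EmptySequence("brute_force_align requires non-empty sequences")
    if n > MAX_BRUTE_FORCE or m > MAX_BRUTE_FORCE:
        raise TooLarge(f"brute force capped at {MAX_BRUTE_FORCE} frames per side")
    C = cost_matrix(S, T, dims=dims, max_angle=max_angle)

    # Step priority measured from the END of the path (matching the
    # backtracking tie rule): diagonal < vertical < horizontal.
    step_rank = {(1, 1): 0, (1, 0): 1, (0, 1): 2}

    best_cost: float | None = None
    best_key: list[int] | None = None
    best_path: list[tuple[int, int]] | None = None
    stack: list[tuple[int, int, float, list[tuple[int, int]]]] = [(0, 0, C[0, 0], [(0, 0)])]
    while stack:
        i, j, cost, path = stack.pop()
        if i == n - 1 and j == m - 1:
            key = [
                step_rank[(b[0] - a[0], b[1] - a[1])]
                for a, b in zip(path[::-1][1:], path[::-1])
            ]
            if (
                best_cost is None
                or cost < best_cost - 1e-12
                or (abs(cost - best_cost) <= 1e-12 and key < best_key)
            ):
                best_cost, best_key, best_path = cost, key, path
            continue
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                stack.append((ni, nj, cost + C[ni, nj], path + [(ni, nj)]))
    assert best_path is not None
    return AlignmentResult(
        distance=float(best_cost),
        path=WarpingPath([(a + 1, b + 1) for a, b in best_path]),
        accumulated=None,
        dims=dims,
        max_angle=max_angle,
    )
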