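"""Performance scoring, expert calibration, and reliability statistics.

The cumulative DTW distance is turned into a percentage by comparing it
with the worst admissible alignment of the same path length.  With each
of ``dims`` angle terms clamped at ``max_angle`` degrees, a path of
length ``s`` can cost at most ``max_angle * dims * s``, so

    raw_pct = 100 * (1 - DTW(S, T) / (max_angle * dims * s))

is 100 for identical motions (up to time warping) and 0 when every
matched dimension sits at the clamp.  No training data enters this
formula; it is a closed-form normalization.

Raw scores systematically run high relative to human raters (even a
poor performance rarely drives bone differences near 90 degrees), so an
affine calibration fitted by ordinary least squares — expert rating
regressed on raw score over a small panel of subjects — maps raw scores
onto the expert scale.  Pearson correlation (with its t statistic) and
the two-way random-effects average-measures intraclass correlation
ICC(2,k) quantify, respectively, agreement between algorithm and
experts and agreement among the experts themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dtw import AlignmentResult, DEFAULT_DIMS, DEFAULT_MAX_ANGLE
from .errors import DegenerateFit, DegenerateInput, InconsistentConfig

__all__ = [
    "PerformanceScore",
    "CalibrationModel",
    "performance_score",
    "fit_calibration",
    "apply_calibration",
    "pearson_r",
    "icc",
    "read_ratings",
]


@dataclass
class PerformanceScore:
    """A 0-100% motion-similarity score.

    ``raw_pct`` is the closed-form percentage; ``calibrated_pct`` is
    filled only after applying a :class:`CalibrationModel`.
    """

    raw_pct: float
    distance: float
    s: int
    dims: int = DEFAULT_DIMS
    max_angle: float = DEFAULT_MAX_ANGLE
    calibrated_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "raw_pct": self.raw_pct,
            "calibrated_pct": self.calibrated_pct,
            "distance_deg": self.distance,
            "path_length": self.s,
            "dims": self.dims,
            "max_angle": self.max_angle,
        }


def performance_score(
    alignment: AlignmentResult,
    dims: int | None = None,
    max_angle: float | None = None,
) -> PerformanceScore:
    """Convert a DTW alignment into the percentage score.

    ``dims`` and ``max_angle`` default to the alignment's own settings;
    passing different values raises :class:`InconsistentConfig`, since
    the normalization must match the cost that produced the distance.
    """
    dims = alignment.dims if dims is None else dims
    max_angle = alignment.max_angle if max_angle is None else max_angle
    if dims != alignment.dims or max_angle != alignment.max_angle:
        raise InconsistentConfig(
            f"score requested with dims={dims}, max_angle={max_angle} but the "
            f"alignment used dims={alignment.dims}, max_angle={alignment.max_angle}"
        )
    s = alignment.s
    raw = 100.0 * (1.0 - alignment.distance / (max_angle * dims * s))
    return PerformanceScore(
        raw_pct=float(raw),
        distance=float(alignment.distance),
        s=s,
        dims=dims,
        max_angle=max_angle,
    )


@dataclass
class CalibrationModel:
    """Affine map from raw algorithm scores to the expert-rating scale,
    fitted by OLS of expert rating on raw score."""

    slope: float
    intercept: float
    n: int
    r: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"slope": self.slope, "intercept": self.intercept, "n": self.n, "r": self.r},
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(slope=float(d["slope"]), intercept=float(d["intercept"]),
                   n=int(d["n"]), r=float(d["r"]))


def fit_calibration(raw_scores, expert_ratings) -> CalibrationModel:
    """Fit ``rating = intercept + slope * raw`` by ordinary least squares."""
    x = np.asarray(raw_scores, dtype=float)
    y = np.asarray(expert_ratings, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DegenerateInput("calibration needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateFit("raw scores are constant; slope undefined")
    fit = stats.linregress(x, y)
    return CalibrationModel(
        slope=float(fit.slope), intercept=float(fit.intercept),
        n=len(x), r=float(fit.rvalue),
    )


def apply_calibration(model: CalibrationModel, score: PerformanceScore) -> PerformanceScore:
    """Return a copy of ``score`` with ``calibrated_pct`` filled.

    The affine prediction is clipped to [0, 100]: the rating scale is
    bounded even though the fitted line is not.
    """
    cal = float(np.clip(model.intercept + model.slope * score.raw_pct, 0.0, 100.0))
    return PerformanceScore(
        raw_pct=score.raw_pct,
        distance=score.distance,
        s=score.s,
        dims=score.dims,
        max_angle=score.max_angle,
        calibrated_pct=cal,
    )


def pearson_r(x, y) -> tuple[float, float, int]:
    """Sample Pearson correlation with its t statistic.

    Returns ``(r, t, df)`` where ``t = r * sqrt(df) / sqrt(1 - r^2)``
    and ``df = n - 2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DegenerateInput("pearson_r needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInput("pearson_r undefined for constant input")
    r = float(stats.pearsonr(x, y).statistic)
    df = len(x) - 2
    if abs(r) >= 1.0:
        t = float(np.inf) if r > 0 else float(-np.inf)
    else:
        t = float(r * np.sqrt(df) / np.sqrt(1.0 - r * r))
    return r, t, df


def _anova_mean_squares(m: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares of a subjects-by-raters table.

    Returns (MSR, MSC, MSE, n, k): rows (subjects), columns (raters),
    residual, and the table shape.
    """
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((m - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(
    ratings,
    form: str = "two_way_random_average",
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Intraclass correlation for inter-rater reliability.

    Parameters
    ----------
    ratings : array-like or DataFrame, shape (subjects, raters)
        Complete table of scores on a common scale; at least 2x2.
    form : str
        Only ``"two_way_random_average"`` — ICC(2,k), two-way random
        effects, absolute agreement, average of k raters — is provided,
        matching the design in which the raters' average serves as the
        gold standard.
    alpha : float
        Confidence level for the interval (default 95% CI).

    Returns
    -------
    (icc_value, ci_low, ci_high)

    Notes
    -----
    Computed from the two-way ANOVA mean squares as
    ``(MSR - MSE) / (MSR + (MSC - MSE) / n)``.  The confidence interval
    uses the standard F-based bounds for the single-rater ICC(2,1),
    stepped up to k raters by the Spearman-Brown relation.
    """
    if form != "two_way_random_average":
        raise ValueError(f"unsupported ICC form: {form!r}")
    m = np.asarray(ratings, dtype=float)
    if isinstance(ratings, pd.DataFrame):
        m = ratings.to_numpy(dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise DegenerateInput("ratings must be at least a 2x2 subjects-by-raters table")
    if not np.all(np.isfinite(m)):
        raise DegenerateInput("ratings table has missing or non-finite cells")
    msr, msc, mse, n, k = _anova_mean_squares(m)
    if np.ptp(m.mean(axis=1)) == 0:
        raise DegenerateInput("zero between-subject variance; ICC undefined")

    icc_k = (msr - mse) / (msr + (msc - mse) / n)
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    if icc_1 >= 1.0:  # perfect agreement; the F interval degenerates
        return float(icc_k), 1.0, 1.0

    # F-based CI for ICC(2,1) (two-way random, absolute agreement,
    # single rater) with Satterthwaite degrees of freedom, then
    # Spearman-Brown step-up to the k-rater average.
    a = k * icc_1 / (n * (1.0 - icc_1))
    b = 1.0 + k * icc_1 * (n - 1.0) / (n * (1.0 - icc_1))
    denom = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    if denom > 0:
        v = (a * msc + b * mse) ** 2 / denom
    else:
        v = (n - 1.0) * (k - 1.0)
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lo1 = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi1 = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )

    def step_up(r1: float) -> float:
        if r1 >= 1.0:
            return 1.0
        return k * r1 / (1.0 + (k - 1.0) * r1)

    return float(icc_k), float(step_up(lo1)), float(step_up(hi1))


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Load a ratings CSV (``subject,rater1,rater2,...``) into a
    subjects-by-raters DataFrame indexed by subject."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise DegenerateInput("ratings CSV needs a subject column and >= 2 raters")
    return df.set_index(df.columns[0])
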