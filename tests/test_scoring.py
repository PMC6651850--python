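import numpy as np
import pytest

from motionscore.dtw import AlignmentResult, WarpingPath
from motionscore.errors import (
    DegenerateFit,
    DegenerateInput,
    InconsistentConfig,
)
from motionscore.scoring import (
    CalibrationModel,
    apply_calibration,
    fit_calibration,
    icc,
    pearson_r,
    performance_score,
    read_ratings,
)


def _alignment(distance, s, dims=9, max_angle=90.0):
    path = WarpingPath([(i, i) for i in range(1, s + 1)])
    return AlignmentResult(distance=distance, path=path, dims=dims, max_angle=max_angle)


class TestPerformanceScore:
    def test_zero_distance_is_100(self):
        assert performance_score(_alignment(0.0, 17)).raw_pct == 100.0

    def test_maximal_distance_is_0(self):
        s = 23
        assert performance_score(_alignment(90.0 * 9 * s, s)).raw_pct == 0.0

    def test_single_pair_45_degree_bone(self):
        # one matched pair, one bone off by 45 deg, nine dimensions:
        # 100 * (1 - 45/810)
        res = performance_score(_alignment(45.0, 1))
        assert res.raw_pct == pytest.approx(100.0 * (1.0 - 45.0 / 810.0), abs=1e-9)
        assert res.raw_pct == pytest.approx(94.44444444444444, abs=1e-8)

    def test_constant_orientation_offset_closed_form(self):
        # every matched pair costs exactly 30 deg along a diagonal path
        n = 50
        res = performance_score(_alignment(30.0 * n, n))
        assert res.raw_pct == pytest.approx(100.0 * (1.0 - 30.0 / 810.0), abs=1e-9)

    def test_eight_dim_normalization(self):
        res = performance_score(_alignment(45.0, 1, dims=8))
        assert res.raw_pct == pytest.approx(100.0 * (1.0 - 45.0 / 720.0), abs=1e-9)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(InconsistentConfig):
            performance_score(_alignment(45.0, 1, dims=9), dims=8)


class TestCalibration:
    def test_noiseless_affine_recovery(self):
        raw = np.array([60.0, 70.0, 80.0, 90.0, 100.0])
        ratings = 0.8 * raw - 10.0
        model = fit_calibration(raw, ratings)
        assert model.slope == pytest.approx(0.8, abs=1e-12)
        assert model.intercept == pytest.approx(-10.0, abs=1e-9)
        assert model.r == pytest.approx(1.0, abs=1e-12)
        score = performance_score(_alignment(0.0, 5))
        cal = apply_calibration(model, score)
        assert cal.calibrated_pct == pytest.approx(70.0, abs=1e-9)

    def test_identity_fit(self):
        raw = np.array([55.0, 65.0, 85.0, 95.0])
        model = fit_calibration(raw, raw)
        assert model.slope == pytest.approx(1.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)

    def test_slope_recovery_under_noise(self):
        """rating = 0.9*raw - 15 + N(0,2) with n=21 subjects: the mean
        fitted slope over 100 replicates stays within 0.1 of 0.9."""
        rng = np.random.default_rng(42)
        slopes = []
        for _ in range(100):
            raw = rng.uniform(60.0, 100.0, size=21)
            rating = 0.9 * raw - 15.0 + rng.normal(0.0, 2.0, size=21)
            slopes.append(fit_calibration(raw, rating).slope)
        assert np.mean(slopes) == pytest.approx(0.9, abs=0.1)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateFit):
            fit_calibration([80.0, 80.0, 80.0], [1.0, 2.0, 3.0])

    def test_calibrated_clipped_to_scale(self):
        model = CalibrationModel(slope=2.0, intercept=0.0, n=5, r=0.9)
        score = performance_score(_alignment(90.0 * 9 * 2 * 0.2, 2))  # raw 80
        assert score.raw_pct == pytest.approx(80.0)
        assert apply_calibration(model, score).calibrated_pct == 100.0

    def test_model_json_roundtrip(self, tmp_path):
        model = CalibrationModel(slope=0.85, intercept=-12.5, n=21, r=0.86)
        model.to_json(tmp_path / "m.json")
        back = CalibrationModel.from_json(tmp_path / "m.json")
        assert back == model


class TestPearson:
    def test_perfect_linear(self):
        r, t, df = pearson_r([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0, abs=1e-12)
        assert df == 2 and t == np.inf

    def test_hand_computed_point_eight(self):
        # covariance sum 4.0 over sqrt(5*5)
        r, t, df = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert t == pytest.approx(0.8 * np.sqrt(2) / np.sqrt(1 - 0.64), abs=1e-9)
        assert df == 2

    def test_antiparallel(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        r, t, df = pearson_r(x, -x)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInput):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestIcc:
    def test_identical_raters_give_one(self):
        m = np.array([[10.0, 10.0, 10.0], [50.0, 50.0, 50.0], [90.0, 90.0, 90.0]])
        value, lo, hi = icc(m)
        assert value == pytest.approx(1.0, abs=1e-12)

    def test_hand_anova_three_by_two(self):
        """3 subjects x 2 raters, mean squares worked by hand:
        MSR=6.1667, MSC=4.1667, MSE=0.1667 -> ICC(2,k) = 6/7.5 = 0.8."""
        m = np.array([[8.0, 9.0], [4.0, 6.0], [6.0, 8.0]])
        value, lo, hi = icc(m)
        assert value == pytest.approx(0.8, abs=1e-12)
        assert lo <= value <= hi

    def test_hand_anova_two_by_two(self):
        # [[1,2],[3,4]]: MSR=4, MSC=1, MSE=0 -> (4-0)/(4+0.5) = 8/9
        value, _, _ = icc(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert value == pytest.approx(8.0 / 9.0, abs=1e-12)

    def test_matches_reference_implementation(self):
        """Cross-check value and 95% CI against pingouin's ICC2k on
        random complete tables."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 15))
            k = int(rng.integers(2, 5))
            subject = rng.normal(0, 10, size=(n, 1))
            m = 60 + subject + rng.normal(0, 5, size=(n, k))
            long = pd.DataFrame({
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": m.ravel(),
            })
            ref = pingouin.intraclass_corr(long, targets="subject",
                                           raters="rater", ratings="score")
            # ICC(A,k) in McGraw-Wong naming == ICC(2,k) in Shrout-Fleiss
            ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
            row = ref[ref["Type"].isin(["ICC2k", "ICC(A,k)"])].iloc[0]
            value, lo, hi = icc(m)
            assert value == pytest.approx(row["ICC"], abs=1e-6)
            # pingouin rounds CI bounds to two decimals
            assert lo == pytest.approx(row[ci_col][0], abs=6e-3)
            assert hi == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_simulated_variance_ratio(self):
        """Subject variance 4, error variance 1, k=3 raters: ICC(2,k)
        should approach k*tau/(k*tau+1) with tau = 4."""
        rng = np.random.default_rng(7)
        k, n = 3, 50
        values = []
        for _ in range(30):
            m = rng.normal(0, 2.0, size=(n, 1)) + rng.normal(0, 1.0, size=(n, k))
            values.append(icc(m)[0])
        expected = (k * 4.0) / (k * 4.0 + 1.0)
        assert np.mean(values) == pytest.approx(expected, abs=0.05)

    def test_zero_between_subject_variance_rejected(self):
        with pytest.raises(DegenerateInput):
            icc(np.array([[5.0, 6.0], [5.0, 6.0], [5.0, 6.0]]))

    def test_too_small_rejected(self):
        with pytest.raises(DegenerateInput):
            icc(np.array([[1.0, 2.0]]))


def test_read_ratings_csv(tmp_path):
    p = tmp_path / "r.csv"
    p.write_text("subject,rater1,rater2,rater3\ns1,80,75,82\ns2,60,64,58\n")
    table = read_ratings(p)
    assert table.shape == (2, 3)
    assert list(table.columns) == ["rater1", "rater2", "rater3"]
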