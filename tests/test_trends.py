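"""Trend fits, DTFL, angle/continuity thresholds, oscillation score and
the 10-type decision tree."""

import math

import numpy as np
import pandas as pd
import pytest

from epitrend import trends
from epitrend.trends import (
    TYPE_NUMBER,
    TrendFit,
    angle_classify,
    classify_gene,
    continuity_ratio,
    dtfl,
    edge_presence_test,
    fc_per_hour,
    fit_trend,
    linear_fit,
    lowess_trend,
    oscillation_score,
    representative_probe,
)


class TestLowessAndDtfl:
    def test_lowess_reproduces_a_line(self):
        y = 0.3 * np.arange(50) + 2.0
        np.testing.assert_allclose(lowess_trend(y), y, atol=1e-6)

    def test_lowess_constant_passthrough(self):
        y = np.full(30, 12.0)
        np.testing.assert_allclose(lowess_trend(y), y)

    def test_lowess_smooths_noisy_sine(self, rng):
        x = np.linspace(0, 4 * np.pi, 179)
        y = np.sin(x) + rng.normal(0, 0.3, x.size)
        fitted = lowess_trend(y)
        assert np.var(y - fitted) < np.var(y)

    def test_dtfl_examples(self):
        y = np.arange(20.0)
        assert dtfl(y, y) == 0.0
        resid = np.tile([0.1, -0.1], 10)
        assert dtfl(y + resid, y) == pytest.approx(0.1)

    def test_dtfl_shift_invariance(self, rng):
        y = rng.normal(12, 0.3, 60)
        f = lowess_trend(y)
        assert dtfl(y + 5.0, f + 5.0) == pytest.approx(dtfl(y, f))


class TestAngle:
    def test_unit_slope_is_45_degrees(self):
        y = 1.0 * np.arange(1, 31)
        label, angle = angle_classify(y)
        assert label == "increasing"
        assert angle == pytest.approx(45.0)

    def test_zero_slope_is_flat(self):
        label, angle = angle_classify(np.full(30, 7.0))
        assert label == "flat" and angle == pytest.approx(0.0, abs=1e-9)

    def test_threshold_is_strict(self):
        # the 0.1-degree boundary itself is flat (strict inequality); the
        # fitted-angle path is checked just inside and outside it
        from epitrend.trends import TrendFit, classify_gene

        trend = TrendFit(np.zeros(3), math.tan(math.radians(0.1)), 0.0, 0.1, 0.0, 1.0)
        cls = classify_gene(trend, False, False, False, False, False, n_samples=179)
        assert cls.category == "constant"
        below = math.tan(math.radians(0.1)) * (1 - 1e-9)
        above = math.tan(math.radians(0.1)) * (1 + 1e-6)
        assert angle_classify(below * np.arange(1, 101))[0] == "flat"
        assert angle_classify(above * np.arange(1, 101))[0] == "increasing"


class TestContinuity:
    def test_perfect_line_is_continuous_with_ratio_one(self):
        y = 2.0 + 0.1 * np.arange(40)
        _, _, lin = linear_fit(y)
        ratio, label = continuity_ratio(y, lin, lowess_trend(y))
        assert ratio == pytest.approx(1.0, abs=1e-6) or label == "continuous"
        assert label == "continuous"

    def test_step_profile_is_discontinuous(self):
        y = np.r_[np.full(40, 12.0), np.full(40, 14.0)]
        _, _, lin = linear_fit(y)
        ratio, label = continuity_ratio(y, lin, lowess_trend(y))
        assert ratio < 0.95 and label == "discontinuous"

    def test_boundary_ratio_is_discontinuous(self):
        # craft residual structure with an exact 0.95 ratio
        y = np.zeros(20)
        linear = np.full(20, 1.0)   # |y - linear| = 1
        lowess = np.full(20, 0.95)  # |y - lowess| = 0.95
        ratio, label = continuity_ratio(y, linear, lowess)
        assert ratio == pytest.approx(0.95)
        assert label == "discontinuous"


class TestOscillation:
    def test_planted_sinusoid_detected(self, rng):
        x = np.arange(179)
        y = 12 + 0.5 * np.sin(2 * np.pi * x / 30) + rng.normal(0, 0.15, 179)
        score, osc = oscillation_score(y)
        assert osc and score > 0.5

    def test_white_noise_not_detected(self, rng):
        y = 12 + rng.normal(0, 0.2, 179)
        score, osc = oscillation_score(y)
        assert not osc

    def test_switch_shaped_bend_not_detected(self):
        # a smooth low-frequency bump in the residuals must not count
        y = np.r_[np.full(90, 8.0), 8.0 + 0.05 * np.arange(89) ** 1.5]
        _, osc = oscillation_score(y)
        assert not osc

    def test_override_list_wins(self, rng):
        y = 12 + rng.normal(0, 0.2, 179)
        _, osc = oscillation_score(y, override=["her1"], gene="her1")
        assert osc


class TestClassifier:
    def _trend(self, angle_deg, ratio):
        return TrendFit(
            lowess_values=np.zeros(3), linear_slope=math.tan(math.radians(angle_deg)),
            linear_intercept=0.0, angle_deg=angle_deg, dtfl=0.1, continuity_ratio=ratio,
        )

    @pytest.mark.parametrize(
        "angle, ratio, edge_on, edge_off, start_valid, stop_valid, osc, expected",
        [
            (0.0, 1.0, False, False, False, False, False, "constant"),
            (0.0, 1.0, False, False, False, False, True, "oscillatory"),
            (2.0, 1.0, True, False, False, False, False, "up_on"),
            (2.0, 1.0, False, False, True, False, False, "up_start"),
            (2.0, 0.99, False, False, False, False, False, "up_continuous"),
            (2.0, 0.80, False, False, False, False, False, "up_discontinuous"),
            (-2.0, 1.0, False, True, False, False, False, "down_off"),
            (-2.0, 1.0, False, False, False, True, False, "down_stop"),
            (-2.0, 0.99, False, False, False, False, False, "down_continuous"),
            (-2.0, 0.80, False, False, False, False, False, "down_discontinuous"),
        ],
    )
    def test_decision_tree_is_total(self, angle, ratio, edge_on, edge_off,
                                    start_valid, stop_valid, osc, expected):
        cls = classify_gene(self._trend(angle, ratio), edge_on, edge_off,
                            start_valid, stop_valid, osc, n_samples=179)
        assert cls.category == expected
        assert cls.type_number == TYPE_NUMBER[expected]
        assert cls.fc_per_hour >= 1.0

    def test_fc_per_hour_closed_forms(self):
        n = 179
        per_rank = 1.0 / ((n - 1) / 3.0)  # one log2 unit per hour
        assert fc_per_hour(per_rank, n) == pytest.approx(2.0)
        assert fc_per_hour(0.0, n) == 1.0
        assert fc_per_hour(-per_rank, n) == pytest.approx(2.0)  # magnitude


class TestEdgePresence:
    annotation = pd.DataFrame(
        {
            "probe_id": ["pA", "pB", "pC"],
            "transcript_id": ["tHigh", "tHigh", "tLow"],
            "gene_id": ["g", "g", "g"],
            "three_prime_rank": [2, 1, 1],
        }
    )

    def _fixture(self, n_present_first15):
        embryos = [f"E{i:03d}" for i in range(40)]
        tx = pd.DataFrame(
            {e: [14.0, 10.0] for e in embryos}, index=["tHigh", "tLow"])
        mask = pd.DataFrame(False, index=["pA", "pB", "pC"], columns=embryos)
        mask.loc["pB", embryos[:n_present_first15]] = True
        mask.loc["pB", embryos[20:]] = True
        mask.loc["pA", embryos] = True
        return tx, mask, embryos

    def test_representative_probe_is_most_3prime_present_of_best_transcript(self):
        tx, mask, _ = self._fixture(5)
        probe = representative_probe("g", tx, self.annotation, mask)
        assert probe == "pB"  # tHigh is best transcript, pB is rank 1 (most 3')

    def test_fewer_than_seven_present_marks_starting(self):
        tx, mask, embryos = self._fixture(6)
        assert edge_presence_test("g", mask, self.annotation, tx, embryos, "first")

    def test_seven_present_is_not_starting(self):
        tx, mask, embryos = self._fixture(7)
        assert not edge_presence_test("g", mask, self.annotation, tx, embryos, "first")

    def test_fully_absent_late_edge_marks_stopping(self):
        tx, mask, embryos = self._fixture(6)
        mask.loc["pB", embryos[20:]] = False
        mask.loc["pA", embryos[-15:]] = False
        assert edge_presence_test("g", mask, self.annotation, tx, embryos, "last")


def test_fit_trend_requires_enough_points():
    with pytest.raises(ValueError):
        fit_trend(np.arange(5.0))
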