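"""Ratio-effect curves, ranges and direction classification."""

import numpy as np
import pytest

from ansaudit import slopes
from ansaudit.slopes import RatioPair

PAIR_1p25_5 = RatioPair(1.25, 5.0)

# labels frozen under the default 0.8 / 0.2 thresholds on [0.04, 1.0]
SIX_PAIR_LABELS = {
    (1.125, 1.4): "negative",
    (1.125, 2.0): "negative",
    (1.125, 4.0): "mixed",
    (1.5, 5.0): "mixed",
    (2.0, 5.0): "mixed",
    (4.0, 9.0): "positive",
}


class TestRatioEffect:
    @pytest.mark.parametrize(
        "w, expected",
        [
            (0.4, 0.69632),   # frozen from the Riemann-grid oracle
            (0.04, 0.00544),  # both overlaps near 0 at tiny w
        ],
    )
    def test_reference_values(self, w, expected):
        assert slopes.ratio_effect(PAIR_1p25_5, w) == pytest.approx(expected, abs=1e-4)

    def test_rejects_unordered_pair(self):
        with pytest.raises(ValueError):
            RatioPair(2.0, 2.0)
        with pytest.raises(ValueError):
            RatioPair(0.5, 2.0)

    def test_vanishes_as_pair_collapses(self):
        assert slopes.ratio_effect((1.5, 1.5 + 1e-9), 0.3) == pytest.approx(0.0, abs=1e-6)

    def test_nonnegative_over_lattice(self):
        ws = np.linspace(0.04, 1.0, 30)
        for pair in slopes.PAPER_RATIO_PAIRS:
            assert np.all(np.asarray(slopes.ratio_effect(pair, ws)) >= 0.0)


class TestLinearSlope:
    def test_two_point_identity_with_ratio_effect(self):
        for w in (0.1, 0.4, 0.8):
            slope = slopes.linear_slope([1.25, 5.0], w)
            effect = slopes.ratio_effect(PAIR_1p25_5, w)
            assert slope == pytest.approx(-effect / 3.75, abs=1e-10)

    def test_matches_closed_form_ols(self):
        from ansaudit.core import overlap

        ratios = np.array([1.125, 1.4, 2.0, 4.0])
        ov = np.array([overlap(r, 0.2) for r in ratios])
        # textbook OLS: cov(x, y) / var(x)
        expected = np.sum((ratios - ratios.mean()) * (ov - ov.mean())) / np.sum(
            (ratios - ratios.mean()) ** 2
        )
        assert slopes.linear_slope(ratios, 0.2) == pytest.approx(expected, abs=1e-12)

    def test_zero_slope_for_flat_overlaps(self):
        # both ratios far out on the flat limb at tiny w: overlaps both ~0
        assert slopes.linear_slope([6.0, 9.0], 0.01) == pytest.approx(0.0, abs=1e-9)

    def test_needs_two_distinct_ratios(self):
        with pytest.raises(ValueError):
            slopes.linear_slope([2.0, 2.0], 0.1)


class TestSlopeCurve:
    def test_single_point_grid(self):
        curve = slopes.slope_curve(PAIR_1p25_5, [0.2])
        assert curve.effects[0] == pytest.approx(slopes.ratio_effect(PAIR_1p25_5, 0.2))

    def test_rise_then_fall_for_mixed_pair(self):
        grid = np.linspace(0.04, 1.0, 200)
        curve = slopes.slope_curve(PAIR_1p25_5, grid)
        peak = int(np.argmax(curve.effects))
        assert 0 < peak < len(grid) - 1
        assert curve.effects[peak] > curve.effects[0]
        assert curve.effects[peak] > curve.effects[-1]

    def test_large_value_pair_is_predominantly_increasing(self):
        grid = np.linspace(0.04, 1.0, 200)
        curve = slopes.slope_curve((4.0, 9.0), grid)
        steps = np.diff(curve.effects)
        assert np.mean(steps > 0) > 0.95

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            slopes.slope_curve(PAIR_1p25_5, [])
        with pytest.raises(ValueError):
            slopes.slope_curve(PAIR_1p25_5, [-0.1, 0.2])


class TestExpectedRange:
    def test_adult_interval_reference_values(self):
        sr = slopes.expected_range(PAIR_1p25_5, (0.1, 0.4))
        assert sr.min_effect == pytest.approx(0.2641, abs=1e-3)
        assert sr.max_effect == pytest.approx(0.6970, abs=1e-3)
        assert 0.40 < sr.range < 0.50

    def test_degenerate_interval_has_zero_range(self):
        sr = slopes.expected_range(PAIR_1p25_5, (0.3, 0.3))
        assert sr.range == 0.0

    def test_rejects_inverted_or_nonpositive_interval(self):
        with pytest.raises(ValueError):
            slopes.expected_range(PAIR_1p25_5, (0.4, 0.1))
        with pytest.raises(ValueError):
            slopes.expected_range(PAIR_1p25_5, (0.0, 0.1))

    def test_range_always_within_unit_interval(self):
        for pair in slopes.PAPER_RATIO_PAIRS:
            sr = slopes.expected_range(pair, (0.04, 1.0), grid_step=5e-3)
            assert 0.0 <= sr.range <= 1.0
            assert sr.range == pytest.approx(sr.max_effect - sr.min_effect)


class TestClassifyDirection:
    @pytest.mark.parametrize("pair, label", sorted(SIX_PAIR_LABELS.items()))
    def test_six_reference_pairs_on_full_range(self, pair, label):
        dc = slopes.classify_direction(pair, (0.04, 1.0))
        assert dc.label == label
        assert 0.0 <= dc.fraction_negative_steps <= 1.0

    def test_thresholds_are_configurable(self):
        dc = slopes.classify_direction((1.125, 2.0), (0.04, 1.0), neg_threshold=0.99)
        assert dc.label == "mixed"

    def test_rising_limb_interval_is_positive(self):
        assert slopes.classify_direction(PAIR_1p25_5, (0.04, 0.3)).label == "positive"


class TestRangeTable:
    def test_structure_and_consistency(self):
        table = slopes.range_table(grid_step=5e-3)
        assert len(table) == 6 * 3
        assert list(table.columns) == ["ratio_pair", "w_lo", "w_hi", "min", "max", "range"]
        row = table[(table.ratio_pair == "2-5") & (table.w_lo == 0.03)]
        assert len(row) == 1
        # spot check against expected_range directly
        sr = slopes.expected_range((2.0, 5.0), (0.03, 0.31), grid_step=5e-3)
        assert row["range"].iloc[0] == pytest.approx(sr.range)
        assert ((table["range"] >= 0) & (table["range"] <= 1)).all()

    def test_custom_interval_row_matches_expected_range(self):
        table = slopes.range_table(
            pairs=[(1.25, 5.0)], w_intervals=[(0.1, 0.4)], grid_step=1e-3
        )
        sr = slopes.expected_range((1.25, 5.0), (0.1, 0.4), grid_step=1e-3)
        assert table["range"].iloc[0] == pytest.approx(sr.range)
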