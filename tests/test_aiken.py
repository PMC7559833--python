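"""Aiken's V, the score interval, and questionnaire summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panelval import (
    ContentValidityModel,
    LikertScale,
    aiken_v,
    rating_frequencies,
    score_ci,
    summarize_questionnaire,
    validate_item,
)
from panelval.rounding import round_half_up, truncate

SCALE = LikertScale(1, 5)


def final_panel(fixture):
    matrix, profiles = fixture
    return ContentValidityModel(matrix, profiles=profiles).fit().panel


class TestFrequencies:
    def test_physician_item_1(self, physicians):
        panel = final_panel(physicians)
        assert rating_frequencies(panel.item_ratings("1"), SCALE) == (0, 0, 0, 2, 8)

    def test_nurse_item_19(self, nurses):
        panel = final_panel(nurses)
        assert rating_frequencies(panel.item_ratings("19"), SCALE) == (0, 1, 0, 1, 8)

    def test_empty_gives_zero_counts(self):
        assert rating_frequencies([], SCALE) == (0, 0, 0, 0, 0)

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError):
            rating_frequencies([0, 3], SCALE)


class TestAikenV:
    def test_physician_item_1(self, physicians):
        panel = final_panel(physicians)
        S, V, mean = aiken_v(panel.item_ratings("1"), SCALE)
        assert (S, V, mean) == (38, 0.95, 4.8)

    def test_nurse_unanimous_item(self, nurses):
        panel = final_panel(nurses)
        S, V, mean = aiken_v(panel.item_ratings("22"), SCALE)
        assert (V, mean) == (1.0, 5.0)

    def test_extremes(self):
        assert aiken_v([1, 1, 1], SCALE)[1] == 0.0
        assert aiken_v([5, 5, 5], SCALE)[1] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aiken_v([], SCALE)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(1, 5), min_size=1, max_size=15),
        st.integers(-3, 3),
    )
    def test_bounds_identity_and_translation_invariance(self, ratings, shift):
        S, V, mean = aiken_v(ratings, SCALE)
        assert 0.0 <= V <= 1.0
        assert V == pytest.approx((mean - SCALE.lowest) / SCALE.span)
        # V recomputed from the frequency table (independent formula)
        freq = rating_frequencies(ratings, SCALE)
        v_from_freq = sum(
            f * (cat - SCALE.lowest) for cat, f in zip(range(1, 6), freq)
        ) / (len(ratings) * SCALE.span)
        assert V == pytest.approx(v_from_freq, abs=1e-12)
        # shifting scale and ratings together changes nothing
        shifted = LikertScale(SCALE.lowest + shift, SCALE.highest + shift)
        S2, V2, _ = aiken_v([r + shift for r in ratings], shifted)
        assert (S2, V2) == (S, pytest.approx(V))


class TestScoreCI:
    def test_published_lower_bound_item_1(self):
        low, high = score_ci(0.95, n=10, k=4)
        assert low == pytest.approx(0.8350, abs=5e-5)
        assert truncate(high, 2) == 0.98

    def test_hand_evaluated_bounds_item_2(self):
        low, high = score_ci(0.85, n=10, k=4)
        assert low == pytest.approx(0.70930, abs=5e-5)
        assert high == pytest.approx(0.92939, abs=5e-5)

    def test_degenerate_endpoints_collapse(self):
        assert score_ci(1.0, 10, 4)[1] == 1.0
        assert score_ci(0.0, 10, 4)[0] == 0.0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        V=st.floats(0, 1, allow_nan=False),
        n=st.integers(1, 50),
        k=st.integers(1, 10),
    )
    def test_score_inversion_identity(self, V, n, k):
        """Both endpoints satisfy the defining equation of the score test."""
        z = 1.96
        low, high = score_ci(V, n, k, z=z)
        assert 0.0 <= low <= V <= high <= 1.0
        for p in (low, high):
            assert (V - p) ** 2 == pytest.approx(z * z * p * (1 - p) / (n * k), abs=1e-9)

    def test_interval_narrows_as_panel_grows(self):
        widths = []
        for n in (5, 10, 20, 40, 80):
            low, high = score_ci(0.85, n, 4)
            widths.append(high - low)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_custom_confidence_uses_normal_quantile(self):
        low90, high90 = score_ci(0.85, 10, 4, confidence=0.90)
        low95, high95 = score_ci(0.85, 10, 4, confidence=0.95)
        assert high90 - low90 < high95 - low95

    def test_invalid_v_rejected(self):
        with pytest.raises(ValueError):
            score_ci(1.2, 10, 4)


class TestValidity:
    @pytest.mark.parametrize(
        "V,expected", [(0.775, True), (0.75, True), (0.7499, False), (1.0, True)]
    )
    def test_threshold_is_inclusive_on_unrounded_v(self, V, expected):
        assert validate_item(V) is expected


class TestSummaries:
    def test_nurse_summary_prints_reported_mean(self, nurses):
        results = ContentValidityModel(*nurses).fit()
        q = results.questionnaire
        assert round_half_up(q.mean_V, 2) == 0.89

    def test_physician_range_prints_reported_bounds(self, physicians):
        q = ContentValidityModel(*physicians).fit().questionnaire
        assert (truncate(q.min_V, 2), truncate(q.max_V, 2)) == (0.77, 0.95)

    def test_single_item_summary(self):
        from panelval import RatingMatrix, analyze_items

        m = RatingMatrix("one", SCALE, ["a", "b"], ["Q1"], [[5], [4]])
        items = analyze_items(m)
        summary = summarize_questionnaire(items)
        assert summary.mean_V == items[0].V
        assert summary.sd_V == 0.0

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            summarize_questionnaire([])
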