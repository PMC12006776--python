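"""Rating, method and topic association statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contratopics.ingest import Review
from contratopics.stats import (RatingHistogram, histogram_mean_sd,
                                method_summary, rating_histogram,
                                round_half_away, scaled_share_table,
                                scaled_topic_share, topic_rating_summary,
                                topic_share_by_method)
from contratopics.topics import UNASSIGNED


def review(rating, method="COCP", rid="1"):
    return Review(record_id=rid, drug_name="x", condition="Birth Control",
                  text="t", rating=rating, date="d", useful_count=0,
                  method=method, unfavorable=rating <= 5)


class TestRounding:
    @pytest.mark.parametrize("x,d,expected", [
        (29.25, 1, 29.3),   # half away from zero, where round() gives 29.2
        (42.705, 1, 42.7),
        (23.664, 0, 24.0),
        (2.5, 0, 3.0),
    ])
    def test_half_away_from_zero(self, x, d, expected):
        assert round_half_away(x, d) == expected


class TestRatingHistogram:
    def test_exact_counts(self):
        hist = rating_histogram([review(1), review(1), review(10)])
        assert hist.counts[1] == 2 and hist.counts[10] == 1
        assert hist.total == 3

    def test_empty_corpus_all_zero(self):
        hist = rating_histogram([])
        assert hist.total == 0
        assert all(c == 0 for c in hist.counts.values())

    def test_conservation(self):
        rng = np.random.default_rng(0)
        reviews = [review(int(r)) for r in rng.integers(1, 11, size=137)]
        assert rating_histogram(reviews).total == 137

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            RatingHistogram({0: 3})


class TestHistogramMeanSd:
    def test_point_mass_at_ten(self):
        m, s = histogram_mean_sd(RatingHistogram({10: 50}))
        assert (m, s) == (10.0, 0.0)

    def test_uniform_closed_form(self):
        m, s = histogram_mean_sd(RatingHistogram({r: 7 for r in range(1, 11)}))
        assert m == pytest.approx(5.5)
        assert s == pytest.approx(math.sqrt(8.25))

    def test_agrees_with_unbinned_oracle(self):
        rng = np.random.default_rng(1)
        ratings = rng.integers(1, 11, size=500)
        hist = rating_histogram([review(int(r)) for r in ratings])
        m, s = histogram_mean_sd(hist)
        assert m == pytest.approx(ratings.mean(), abs=1e-12)
        assert s == pytest.approx(ratings.std(ddof=0), abs=1e-12)

    def test_empty_is_fatal(self):
        with pytest.raises(ValueError):
            histogram_mean_sd(RatingHistogram({}))


class TestMethodSummary:
    def test_toy_unfavorable_share(self):
        reviews = [review(r, "POP", str(i))
                   for i, r in enumerate((2, 3, 8, 9))]
        tbl = method_summary(reviews)
        assert tbl.loc["POP", "unfavorable_share"] == 0.5
        assert tbl.loc["POP", "n_reviews"] == 4

    def test_counts_conserve_and_cross_check_flags(self):
        rng = np.random.default_rng(2)
        methods = ["COCP", "POP", "shot"]
        reviews = [review(int(r), methods[i % 3], str(i))
                   for i, r in enumerate(rng.integers(1, 11, size=90))]
        tbl = method_summary(reviews)
        assert tbl["n_reviews"].sum() == 90
        for m in methods:
            flags = [r.unfavorable for r in reviews if r.method == m]
            assert tbl.loc[m, "n_unfavorable"] == sum(flags)
            assert tbl.loc[m, "unfavorable_share"] == pytest.approx(
                sum(flags) / len(flags))


class TestTopicShares:
    def test_toy_shares(self):
        reviews = [review(2, "copper IUD", str(i)) for i in range(3)]
        tbl = topic_share_by_method(reviews, [0, 0, 1],
                                    topic_names=["cramps", "libido"])
        assert tbl.loc["copper IUD", "cramps"] == pytest.approx(2 / 3)
        assert tbl.loc["copper IUD", "libido"] == pytest.approx(1 / 3)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        methods = ["COCP", "POP", "patch"]
        reviews = [review(3, methods[i % 3], str(i)) for i in range(60)]
        labels = rng.integers(0, 4, size=60)
        tbl = topic_share_by_method(reviews, labels)
        np.testing.assert_allclose(tbl.sum(axis=1), 1.0, atol=1e-12)

    def test_unassigned_documents_excluded(self):
        reviews = [review(2, "shot", str(i)) for i in range(4)]
        tbl = topic_share_by_method(reviews, [0, 1, UNASSIGNED, 0])
        np.testing.assert_allclose(tbl.loc["shot"].sum(), 1.0)
        assert tbl.loc["shot", 0] == pytest.approx(2 / 3)


class TestScaledShare:
    def test_worked_percentages(self):
        # two dominant-topic shares of 24% each, unfavorable rate 49.3%
        val = scaled_topic_share(0.24 + 0.24, 0.493)
        assert val == pytest.approx(0.23664)
        assert round_half_away(100 * val, 0) == 24

    @pytest.mark.parametrize("share,rate,expected", [(0.0, 0.8, 0.0),
                                                     (1.0, 0.37, 0.37)])
    def test_edge_shares(self, share, rate, expected):
        assert scaled_topic_share(share, rate) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_never_exceeds_unfavorable_rate(self, share, rate):
        assert scaled_topic_share(share, rate) <= rate

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            scaled_topic_share(1.2, 0.5)
        with pytest.raises(ValueError):
            scaled_topic_share(0.5, -0.1)

    def test_table_application(self):
        reviews = [review(2, "POP", "1"), review(3, "POP", "2"),
                   review(9, "POP", "3"), review(8, "POP", "4")]
        methods = method_summary(reviews)
        unfav = [r for r in reviews if r.unfavorable]
        shares = topic_share_by_method(unfav, [0, 1])
        scaled = scaled_share_table(shares, methods)
        # unfavorable rate is 1/2, each topic share 1/2 -> scaled 1/4
        assert scaled.loc["POP", 0] == pytest.approx(0.25)


class TestTopicRatingSummary:
    def test_toy_quartiles_and_mean(self):
        reviews = [review(r, rid=str(i)) for i, r in enumerate((1, 1, 3, 5))]
        tbl = topic_rating_summary(reviews, [0, 0, 0, 0])
        assert tbl.loc[0, "median"] == 2.0
        assert tbl.loc[0, "mean"] == 2.5
        assert tbl.loc[0, "q1"] == 1.0
        assert tbl.loc[0, "n"] == 4

    def test_identical_ratings_degenerate(self):
        reviews = [review(4, rid=str(i)) for i in range(5)]
        tbl = topic_rating_summary(reviews, [0] * 5)
        assert tbl.loc[0, "sd"] == 0.0
        assert tbl.loc[0, "q1"] == tbl.loc[0, "median"] == tbl.loc[0, "q3"] == 4.0

    def test_quartile_ordering_property(self):
        rng = np.random.default_rng(4)
        reviews = [review(int(r), rid=str(i))
                   for i, r in enumerate(rng.integers(1, 6, size=80))]
        labels = rng.integers(0, 3, size=80)
        tbl = topic_rating_summary(reviews, labels)
        assert (tbl["q1"] <= tbl["median"]).all()
        assert (tbl["median"] <= tbl["q3"]).all()
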