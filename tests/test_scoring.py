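"""TAS score aggregation, anomaly flags, calendar/clock tables, correlation."""

import datetime

import numpy as np
import pandas as pd
import pytest

from tas.scoring import (
    correlate_with_surveys,
    daily_score_table,
    flag_anomalies,
    hourly_score_distribution,
    tas_scores,
)
from tas.types import SegmentId, SimilarityMatrix

from _oracles import pearson_closed_form


def matrix_from(values, dates=None, slots=None, key="g", metric="dtw"):
    values = np.asarray(values, float)
    l = len(values)
    dates = dates or [datetime.date(2021, 3, 1) + datetime.timedelta(days=i) for i in range(l)]
    slots = slots or [0] * l
    ids = [SegmentId(d, s) for d, s in zip(dates, slots)]
    return SimilarityMatrix(group_key=key, metric=metric, values=values, segment_ids=ids)


def score_table(scores, key="g", dates=None, slots=None):
    l = len(scores)
    return pd.DataFrame(
        {
            "group_key": key,
            "date": dates or [datetime.date(2021, 3, 1) + datetime.timedelta(days=i) for i in range(l)],
            "slot": slots or [0] * l,
            "metric": "dtw",
            "score": scores,
            "is_anomaly": False,
        }
    )


class TestTasScores:
    def test_row_mean_example(self):
        t = tas_scores(matrix_from([[0, 1, 4], [1, 0, 5], [4, 5, 0]]), "mean")
        np.testing.assert_allclose(t["score"], [2.5, 3.0, 4.5])
        assert t.loc[t["score"].idxmax(), "date"] == datetime.date(2021, 3, 3)

    def test_median_aggregation(self):
        t = tas_scores(matrix_from([[0, 1, 4], [1, 0, 5], [4, 5, 0]]), "median")
        np.testing.assert_allclose(t["score"], [2.5, 3.0, 4.5])

    def test_all_zero_matrix(self):
        t = tas_scores(matrix_from(np.zeros((4, 4))))
        np.testing.assert_array_equal(t["score"], 0.0)

    def test_permutation_equivariance(self):
        v = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], float)
        perm = [2, 0, 1]
        base = tas_scores(matrix_from(v))
        shuffled = tas_scores(
            matrix_from(v[np.ix_(perm, perm)],
                        dates=[base["date"].iloc[p] for p in perm])
        )
        merged = base.merge(shuffled, on="date", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["score_a"], merged["score_b"])

    def test_off_diagonal_shift_linearity(self):
        v = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], float)
        shifted = v + 2.0
        np.fill_diagonal(shifted, 0.0)
        a = tas_scores(matrix_from(v))["score"]
        b = tas_scores(matrix_from(shifted))["score"]
        np.testing.assert_allclose(b, a + 2.0)

    def test_missing_entries_excluded(self):
        v = np.array([[0, 1, np.nan], [1, 0, np.nan], [np.nan, np.nan, 0]])
        t = tas_scores(matrix_from(v))
        # third row has no usable partner and is omitted
        assert len(t) == 2
        np.testing.assert_allclose(t["score"], [1.0, 1.0])


class TestFlagAnomalies:
    def test_tukey_flags_only_the_outlier(self):
        t = flag_anomalies(score_table([1.0, 1.0, 1.0, 10.0]), "tukey", k=1.5)
        assert t["is_anomaly"].tolist() == [False, False, False, True]

    def test_identical_scores_no_flags(self):
        t = flag_anomalies(score_table([2.0] * 5), "tukey")
        assert not t["is_anomaly"].any()

    def test_quantile_counts(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        t = flag_anomalies(score_table(scores), "quantile", q=0.75)
        assert int(t["is_anomaly"].sum()) == 2
        assert t.loc[t["is_anomaly"], "score"].tolist() == [7.0, 8.0]

    def test_quantile_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.exponential(size=12)
        a = flag_anomalies(score_table(list(scores)), "quantile", q=0.75)
        b = flag_anomalies(score_table(list(np.log1p(scores) * 7 + 2)), "quantile", q=0.75)
        assert a["is_anomaly"].tolist() == b["is_anomaly"].tolist()

    def test_fewer_than_three_scores_unflagged(self):
        t = flag_anomalies(score_table([1.0, 100.0]))
        assert not t["is_anomaly"].any()

    def test_groups_flagged_independently(self):
        t = pd.concat(
            [score_table([1.0, 1.0, 1.0, 10.0], key="a"),
             score_table([10.0, 10.0, 10.0, 10.0], key="b")],
            ignore_index=True,
        )
        out = flag_anomalies(t)
        assert int(out["is_anomaly"].sum()) == 1
        assert out.loc[out["is_anomaly"], "group_key"].tolist() == ["a"]


class TestDailyTable:
    def test_whole_day_identity_layout(self):
        daily = daily_score_table([score_table([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])])
        assert len(daily) == 7
        np.testing.assert_allclose(daily.to_numpy(), np.arange(1.0, 8.0))

    def test_hourly_scores_averaged_per_date(self):
        d = datetime.date(2021, 3, 1)
        t = score_table([2.0, 4.0, 9.0], dates=[d, d, d], slots=[8, 9, 10])
        daily = daily_score_table([t])
        assert daily[d] == pytest.approx(5.0)

    def test_missing_dates_blank(self):
        d0, d2 = datetime.date(2021, 3, 1), datetime.date(2021, 3, 3)
        daily = daily_score_table([score_table([1.0, 3.0], dates=[d0, d2])])
        assert len(daily) == 3
        assert np.isnan(daily[datetime.date(2021, 3, 2)])

    def test_empty_input(self):
        assert daily_score_table([]).empty


class TestHourlyProfile:
    def test_exactly_24_slots(self):
        prof = hourly_score_distribution([score_table([1.0, 2.0], slots=[3, 17])])
        assert prof["slot"].tolist() == list(range(24))
        assert prof["mean_score"].notna().sum() == 2

    def test_rank_identifies_most_dissimilar_period(self):
        prof = hourly_score_distribution([score_table([1.0, 9.0, 2.0], slots=[3, 17, 20])])
        assert prof.loc[prof["slot"] == 17, "rank"].item() == 1.0

    def test_empty_slots_marked_missing(self):
        prof = hourly_score_distribution([])
        assert prof["mean_score"].isna().all() and (prof["n"] == 0).all()


class TestCorrelation:
    def test_perfect_linearity(self):
        scores = pd.Series([1.0, 2.0, 3.0],
                           index=[datetime.date(2021, 3, 1) + datetime.timedelta(days=i)
                                  for i in range(3)])
        surveys = pd.DataFrame({"date": scores.index, "score": [2.0, 4.0, 6.0]})
        rep = correlate_with_surveys(scores, surveys)
        assert rep["rho"] == pytest.approx(1.0) and rep["n_pairs"] == 3

    def test_matches_closed_form(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [3.0, 1.0, 4.0, 2.0]
        dates = [datetime.date(2021, 3, 1) + datetime.timedelta(days=i) for i in range(4)]
        rep = correlate_with_surveys(pd.Series(x, index=dates),
                                     pd.DataFrame({"date": dates, "score": y}))
        assert rep["rho"] == pytest.approx(pearson_closed_form(x, y), abs=1e-12)

    def test_unmatched_survey_dates_dropped(self):
        dates = [datetime.date(2021, 3, 1) + datetime.timedelta(days=i) for i in range(4)]
        scores = pd.Series([1.0, 2.0, 4.0], index=dates[:3])
        surveys = pd.DataFrame({"date": dates, "score": [1.0, 2.0, 4.0, 99.0]})
        rep = correlate_with_surveys(scores, surveys)
        assert rep["n_pairs"] == 3 and rep["rho"] == pytest.approx(1.0)

    def test_instrument_filter(self):
        dates = [datetime.date(2021, 3, 1) + datetime.timedelta(days=i) for i in range(3)]
        surveys = pd.DataFrame({
            "date": dates * 2,
            "instrument": ["daily_mood"] * 3 + ["daily_anxiety"] * 3,
            "score": [1.0, 2.0, 3.0, 3.0, 2.0, 1.0],
        })
        scores = pd.Series([1.0, 2.0, 3.0], index=dates)
        assert correlate_with_surveys(scores, surveys, "daily_mood")["rho"] == pytest.approx(1.0)
        assert correlate_with_surveys(scores, surveys, "daily_anxiety")["rho"] == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        dates = [datetime.date(2021, 3, 1), datetime.date(2021, 3, 2)]
        with pytest.raises(ValueError):
            correlate_with_surveys(pd.Series([1.0, 2.0], index=dates),
                                   pd.DataFrame({"date": dates, "score": [1.0, 2.0]}))

    def test_zero_variance_rejected(self):
        dates = [datetime.date(2021, 3, 1) + datetime.timedelta(days=i) for i in range(4)]
        with pytest.raises(ValueError):
            correlate_with_surveys(pd.Series([2.0] * 4, index=dates),
                                   pd.DataFrame({"date": dates, "score": [1.0, 2.0, 3.0, 4.0]}))

    def test_per_participant_pairing(self):
        dates = [datetime.date(2021, 3, 1) + datetime.timedelta(days=i) for i in range(4)]
        surveys = pd.DataFrame({
            "participant_id": ["a"] * 4 + ["b"] * 4,
            "date": dates * 2,
            "score": [1.0, 2.0, 3.0, 4.0, 4.0, 3.0, 2.0, 1.0],
        })
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=dates)
        rep = correlate_with_surveys(scores, surveys, pairing="per_participant")
        assert rep["rho"] == pytest.approx(0.0, abs=1e-12)  # mean of +1 and -1
        assert rep["n_pairs"] == 8
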