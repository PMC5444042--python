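"""Low-activeness labeling, fusion rules and precision/recall scoring."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest

import activeness as act
from activeness.preprocessing import ActivenessSeries, CHANNELS
from oracles import brute_def1_labels, brute_vote

T0 = pd.Timestamp("2016-01-04 00:00:00")


def series_from_channel(values, channel="steps", fill=1.0):
    """One-channel series; the two other channels are constant."""
    values = np.asarray(values, dtype=float)
    mat = np.full((len(values), 3), fill)
    mat[:, CHANNELS.index(channel)] = values
    return ActivenessSeries(T0, mat)


def label_set(labels, channel="steps", window_len=15):
    return act.WindowLabelSet(
        start_time=T0, window_len=window_len,
        labels=np.asarray(labels, dtype=bool), channel=channel, source="true_data",
    )


class TestDailyAverage:
    def test_constant_day(self):
        s = series_from_channel(np.full(1440, 7.0))
        assert act.daily_average(s, "steps", "2016-01-04") == 7.0

    def test_arithmetic_sequence_day(self):
        s = series_from_channel(np.arange(1440.0))
        assert act.daily_average(s, "steps", "2016-01-04") == pytest.approx(719.5)

    def test_missing_day_rejected(self):
        s = series_from_channel(np.arange(1440.0))
        with pytest.raises(ValueError, match="no minutes"):
            act.daily_average(s, "steps", "2016-02-01")


class TestDefinition1:
    def _window(self, n_below):
        # one day whose first window has n_below minutes far below the mean
        values = np.full(1440, 100.0)
        values[:n_below] = 0.0
        return series_from_channel(values)

    def test_eleven_of_fifteen_below_marks_less_active(self):
        labels = act.label_windows_def1(self._window(11), "steps")
        assert labels.labels[0]

    def test_ten_of_fifteen_is_not_enough(self):
        labels = act.label_windows_def1(self._window(10), "steps")
        assert not labels.labels[0]

    def test_all_minutes_equal_to_average_not_less_active(self):
        labels = act.label_windows_def1(series_from_channel(np.full(1440, 5.0)), "steps")
        assert not labels.labels.any()

    def test_matches_brute_force_enumerator(self, rng):
        for _ in range(500):
            n_days = int(rng.integers(1, 3))
            n = n_days * 1440 if rng.random() < 0.2 else int(rng.integers(30, 200))
            values = rng.choice([0.0, 1.0, 2.0, 5.0], size=n)
            s = series_from_channel(values)
            got = act.label_windows_def1(s, "steps").labels
            day_means = (
                pd.Series(values).groupby(np.asarray(s.index.date)).transform("mean").to_numpy()
            )
            expected = brute_def1_labels(values, day_means, 15, 0.70)
            np.testing.assert_array_equal(got, expected)

    def test_midnight_straddling_window_uses_each_minutes_own_day(self, rng):
        # start at 00:10 so some 15-min windows straddle midnight
        values = rng.choice([0.0, 3.0, 8.0], size=2880)
        mat = np.tile(values[:, None], (1, 3))
        s = ActivenessSeries(T0 + pd.Timedelta(minutes=10), mat)
        got = act.label_windows_def1(s, "steps").labels
        day_means = (
            pd.Series(values).groupby(np.asarray(s.index.date)).transform("mean").to_numpy()
        )
        expected = brute_def1_labels(values, day_means, 15, 0.70)
        np.testing.assert_array_equal(got, expected)

    def test_raising_frac_never_adds_positives(self, rng):
        values = rng.random(600) * 10
        s = series_from_channel(values)
        counts = [
            act.label_windows_def1(s, "steps", frac=f).labels.sum()
            for f in (0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFusion:
    def test_definition2_is_intersection(self):
        a = label_set([True, True, False], "heart_rate")
        b = label_set([True, True, False], "calories")
        c = label_set([True, False, False], "steps")
        fused = act.label_windows_def2([a, b, c])
        np.testing.assert_array_equal(fused.labels, [True, False, False])
        assert fused.channel == "fused"

    def test_definition2_positives_subset_of_each_channel(self, rng):
        sets = [
            label_set(rng.random(50) < 0.4, c) for c in CHANNELS
        ]
        fused = act.label_windows_def2(sets)
        for s in sets:
            assert not (fused.labels & ~s.labels).any()

    def test_vote_truth_table_exhaustive(self):
        for k in (1, 2, 3):
            for combo in itertools.product([False, True], repeat=3):
                sets = [label_set([v], c) for v, c in zip(combo, CHANNELS)]
                got = act.vote_windows(sets, k=k).labels[0]
                assert got == brute_vote(*combo, k=k)

    def test_vote_boundaries_are_or_and_and(self, rng):
        sets = [label_set(rng.random(40) < 0.5, c) for c in CHANNELS]
        np.testing.assert_array_equal(
            act.vote_windows(sets, k=1).labels,
            np.logical_or.reduce([s.labels for s in sets]),
        )
        np.testing.assert_array_equal(
            act.vote_windows(sets, k=3).labels,
            act.label_windows_def2(sets).labels,
        )

    def test_misaligned_sets_rejected(self):
        a = label_set([True, False], "heart_rate")
        b = label_set([True], "calories")
        c = label_set([True, False], "steps")
        with pytest.raises(ValueError, match="aligned"):
            act.vote_windows([a, b, c])


class TestScoring:
    def test_perfect_prediction(self):
        t = label_set([True, False, True])
        score = act.score_prf(t, t)
        assert (score.precision, score.recall, score.f1) == (1.0, 1.0, 1.0)

    def test_all_negative_prediction_warns_zero(self, caplog):
        pred = label_set([False, False])
        truth = label_set([True, False])
        with caplog.at_level(logging.WARNING, logger="activeness.windows"):
            score = act.score_prf(pred, truth)
        assert score.precision == 0.0 and score.recall == 0.0 and score.f1 == 0.0
        assert "precision" in caplog.text

    def test_hand_computed_counts(self):
        pred = label_set([True, True, True, False, False, False])
        truth = label_set([True, True, False, True, True, False])
        score = act.score_prf(pred, truth)
        assert (score.tp, score.fp, score.fn) == (2, 1, 2)
        assert score.precision == pytest.approx(2 / 3)
        assert score.recall == pytest.approx(0.5)
        assert score.f1 == pytest.approx(4 / 7)


def _toy_series(rng, minutes=1440):
    """Channels share one low/high pattern (scaled differently) so that
    definition-2 positives actually exist."""
    base = rng.choice([0.0, 0.2, 5.0, 9.0], size=minutes)
    mat = base[:, None] * np.array([10.0, 5.0, 100.0]) + [1.0, 0.5, 0.0]
    return ActivenessSeries(T0, mat)


class TestApproaches:
    def test_perfect_forecaster_scores_one(self, rng):
        truth = _toy_series(rng)
        scores = act.evaluate_approach1(truth, truth, definition=1)
        assert set(scores) == set(CHANNELS)
        for s in scores.values():
            assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)
        fused = act.evaluate_approach1(truth, truth, definition=2)
        assert fused.f1 == 1.0
        # approach 2 scores a 2-of-3 vote against the 3-of-3 truth: a perfect
        # forecaster recovers every true window (recall 1) but may flag extra
        # windows where exactly two channels are low
        vote_score = act.evaluate_approach2(truth, truth)
        assert vote_score.recall == 1.0
        assert vote_score.fn == 0

    def test_output_shape_per_definition(self, rng):
        truth = _toy_series(rng)
        pred = _toy_series(rng)
        assert len(act.evaluate_approach1(pred, truth, definition=1)) == 3
        assert isinstance(act.evaluate_approach1(pred, truth, definition=2), act.PrfScore)

    def test_anticorrelated_forecaster_has_zero_recall(self):
        # truth: first hour low (positives), rest high; forecast inverted
        truth_vals = np.concatenate([np.zeros(60), np.full(1380, 100.0)])
        pred_vals = np.concatenate([np.full(60, 100.0), np.zeros(1380)])
        truth = series_from_channel(truth_vals)
        pred = series_from_channel(pred_vals)
        score = act.evaluate_approach1(pred, truth, definition=1)["steps"]
        assert score.recall == 0.0

    def test_misaligned_series_rejected(self, rng):
        truth = _toy_series(rng)
        pred = ActivenessSeries(T0 + pd.Timedelta(minutes=1), truth.values.copy())
        with pytest.raises(ValueError, match="aligned"):
            act.evaluate_approach1(pred, truth)

    def test_vote_recovers_truth_when_one_channel_always_wrong(self, rng):
        # two channels forecast perfectly, one is inverted everywhere: the
        # 2-of-3 vote must equal the definition-2 truth exactly
        truth = _toy_series(rng, minutes=60)  # 4 windows
        pred_vals = truth.values.copy()
        pred_vals[:, 0] = truth.values[:, 0].max() + 1 - truth.values[:, 0]
        pred = ActivenessSeries(T0, pred_vals)
        score = act.evaluate_approach2(pred, truth)
        true_sets = [act.label_windows_def1(truth, c) for c in CHANNELS]
        fused_truth = act.label_windows_def2(true_sets)
        pred_sets = [
            act.label_windows_def1(pred, c, source="predicted") for c in CHANNELS
        ]
        voted = act.vote_windows(pred_sets, k=2)
        expected = act.score_prf(voted, fused_truth)
        assert score == expected

    def test_degenerate_truth_without_positives(self, caplog, rng):
        truth = series_from_channel(np.full(60, 5.0))
        pred = series_from_channel(rng.random(60))
        with caplog.at_level(logging.WARNING, logger="activeness.windows"):
            score = act.evaluate_approach2(pred, truth)
        assert score.recall == 0.0
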