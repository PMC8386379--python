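"""Voice-diary, text and call features; the lexicon sentiment scorer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenoweek.diary_comms import (
    call_features,
    count_emoji,
    diary_features,
    sentiment_score,
    text_features,
)


class TestSentiment:
    def test_all_positive_tokens_hit_ceiling(self):
        lex = {"a": 1.0, "b": 1.0}
        assert sentiment_score(["a", "b", "a"], lex) == 1.0

    def test_empty_tokens_neutral(self, lexicon):
        assert sentiment_score([], lexicon) == 0.0

    def test_out_of_lexicon_tokens_ignored(self):
        lex = {"up": 1.0, "down": -0.5}
        assert sentiment_score(["up", "down", "zzz"], lex) == pytest.approx(0.25)

    def test_packaged_lexicon_scores_bounded(self, lexicon):
        assert all(-1.0 <= s <= 1.0 for s in lexicon.values())

    @given(tokens=st.lists(st.sampled_from(["good", "bad", "love", "hopeless", "xyzzy", "the"]), max_size=50))
    def test_score_bounded_for_arbitrary_streams(self, lexicon, tokens):
        assert -1.0 <= sentiment_score(tokens, lexicon) <= 1.0


class TestDiary:
    def test_words_per_minute_unit_ratio(self, lexicon):
        f = diary_features(["w"] * 120, 60.0, [], lexicon)
        assert f.words_per_minute == 120.0

    def test_mean_pause(self, lexicon):
        f = diary_features(["w"], 30.0, [1.0, 3.0], lexicon)
        assert f.mean_pause_s == 2.0

    def test_no_pauses_is_zero(self, lexicon):
        assert diary_features(["w"], 30.0, [], lexicon).mean_pause_s == 0.0

    def test_nonpositive_duration_rejected(self, lexicon):
        with pytest.raises(ValueError):
            diary_features(["w"], 0.0, [], lexicon)

    def test_generator_diaries_track_severity(self, lexicon):
        """Depressed-arm diaries score lower sentiment than control-arm
        diaries on a synthetic cohort (effect-sign recovery)."""
        from phenoweek import CohortConfig
        from phenoweek.simulate import iter_participants

        cfg = CohortConfig(n_participants=20, n_weeks=2, seed=55)
        by_arm = {"depressed": [], "control": []}
        for p in iter_participants(cfg):
            for rec in p.streams["diary"].itertuples():
                by_arm[p.arm].append(sentiment_score(rec.transcript.split(), lexicon))
        assert np.mean(by_arm["depressed"]) < np.mean(by_arm["control"])


def messages(rows):
    return pd.DataFrame(rows, columns=["direction", "body"])


class TestTexts:
    def test_no_outgoing_messages(self, lexicon):
        f = text_features(messages([]), lexicon)
        assert f == {
            "text_message_count": 0.0,
            "text_message_emoji_count": 0.0,
            "text_message_body_size": 0.0,
            "outgoing_text_sentiment": 0.0,
        }

    def test_incoming_only_day_equals_empty_day(self, lexicon):
        f = text_features(messages([("incoming", "good love")]), lexicon)
        assert f == text_features(messages([]), lexicon)

    def test_emoji_counted_across_messages(self, lexicon):
        f = text_features(
            messages([("outgoing", "hi \U0001F600\U0001F60A\U0001F62D"), ("outgoing", "ok \U0001F44D")]),
            lexicon,
        )
        assert f["text_message_emoji_count"] == 4.0
        assert f["text_message_count"] == 2.0

    def test_sentiment_over_concatenated_tokens(self):
        lex = {"up": 1.0, "down": -0.5}
        f = text_features(messages([("outgoing", "up zz"), ("outgoing", "down")]), lex)
        assert f["outgoing_text_sentiment"] == pytest.approx(0.25)

    def test_body_size_total_characters(self, lexicon):
        f = text_features(messages([("outgoing", "abcd"), ("outgoing", "efg")]), lexicon)
        assert f["text_message_body_size"] == 7.0

    def test_emoji_detection_ranges(self):
        assert count_emoji("plain text.") == 0
        assert count_emoji("\U0001F600 and ❤") == 2


def call_log(rows):
    return pd.DataFrame(rows, columns=["direction", "outcome", "ring_s", "duration_s"])


class TestCalls:
    def test_missed_call_ring_unit_conversion(self):
        f = call_features(call_log([("incoming", "missed", 90.0, 0.0)]))
        assert f["ring_until_missed_minutes"] == 1.5

    def test_answered_only_has_zero_missed_ring(self):
        f = call_features(call_log([("incoming", "answered", 10.0, 120.0)]))
        assert f["ring_until_missed_minutes"] == 0.0

    def test_mixed_log_hand_summed(self):
        log = call_log(
            [
                ("incoming", "answered", 8.0, 60.0),
                ("outgoing", "answered", 5.0, 120.0),
                ("incoming", "answered", 6.0, 60.0),
                ("incoming", "missed", 30.0, 0.0),
                ("incoming", "missed", 30.0, 0.0),
            ]
        )
        f = call_features(log)
        assert f["phone_call_count"] == 5.0
        assert f["incoming_phone_call_duration"] == 120.0
        assert f["outgoing_phone_call_duration"] == 120.0
        assert f["ring_until_missed_minutes"] == 1.0

    def test_negative_intervals_rejected(self):
        with pytest.raises(ValueError):
            call_features(call_log([("incoming", "answered", -1.0, 10.0)]))

    def test_permutation_invariance(self):
        rows = [
            ("incoming", "answered", 8.0, 60.0),
            ("outgoing", "answered", 5.0, 120.0),
            ("incoming", "missed", 45.0, 0.0),
        ]
        f1 = call_features(call_log(rows))
        f2 = call_features(call_log(rows[::-1]))
        assert f1 == f2


def test_weekly_comm_features_match_bruteforce_daily_recomputation(lexicon):
    """The vectorized pipeline path equals per-day recomputation with the
    reference daily functions, averaged over sufficient days."""
    from phenoweek import CohortConfig, MissingnessConfig
    from phenoweek.featurize import featurize_participant
    from phenoweek.filtering import aggregate_week
    from phenoweek.simulate import iter_participants

    cfg = CohortConfig(n_participants=1, n_weeks=2, seed=99, missingness=MissingnessConfig.none())
    p = next(iter_participants(cfg))
    recs = featurize_participant(
        p.streams, cfg.start_date, cfg.n_weeks, p.place_tags, participant_id=p.participant_id
    )
    start = pd.Timestamp(cfg.start_date)

    calls = p.streams["calls"]
    call_day = (pd.DatetimeIndex(calls["timestamp"]).normalize() - start).days
    texts = p.streams["texts"]
    text_day = (pd.DatetimeIndex(texts["timestamp"]).normalize() - start).days
    for rec in recs:
        w = rec["week_index"]
        days = range(w * 7, w * 7 + 7)
        call_daily = [call_features(calls[call_day == d])["phone_call_count"] for d in days]
        text_daily = [
            text_features(texts[text_day == d], lexicon)["text_message_emoji_count"] for d in days
        ]
        mask = [True] * 7  # zero missingness: every day sufficient
        assert rec["features"]["phone_call_count"] == pytest.approx(aggregate_week(call_daily, mask))
        assert rec["features"]["text_message_emoji_count"] == pytest.approx(aggregate_week(text_daily, mask))
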