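import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ssritweets.features import (
    FEATURE_COLUMNS,
    TweetFeaturizer,
    extract_features,
    lexical_features,
    pos_features,
    temporal_features,
)
from ssritweets.text import DictionaryTagger, default_lexicons, default_tagger

from conftest import make_frame


def labeled(rows):
    """rows: (text, iso_ts, offset) all unknown_treatment for user u."""
    return make_frame(
        [("u", ts, off, text, False, "unknown_treatment") for text, ts, off in rows]
    )


class TestTemporalFeatures:
    def test_daytime_boundary_at_8am(self):
        frame = labeled(
            [
                ("hola", "2020-06-01T07:59:00Z", 0),
                ("hola", "2020-06-01T08:00:00Z", 0),
                ("hola", "2020-06-01T23:59:00Z", 0),
            ]
        )
        out = temporal_features(frame, "unknown_treatment")
        assert out["pct_daytime"] == pytest.approx(66.6667, abs=1e-3)

    def test_tweets_per_day_over_observed_days(self):
        rows = []
        for d in range(1, 6):
            for _ in range(2):
                rows.append(("hola", f"2020-06-{d:02d}T12:00:00Z", 0))
        out = temporal_features(labeled(rows), "unknown_treatment")
        assert out["tweets_per_day"] == 2.0

    def test_weekday_percentage(self):
        # 2020-06-01 Mon, 02 Tue, 06 Sat, 07 Sun
        rows = [("hola", f"2020-06-{d:02d}T12:00:00Z", 0) for d in (1, 2, 6, 7)]
        out = temporal_features(labeled(rows), "unknown_treatment")
        assert out["pct_weekday"] == 50.0
        assert out["tweets_per_weekday_day"] == pytest.approx(2 / 2)
        assert out["tweets_per_weekend_day"] == pytest.approx(2 / 2)

    def test_local_clock_drives_hour(self):
        # 23:30 UTC at -7200 is 21:30 local (daytime); at +3600 is 00:30 (night)
        f1 = labeled([("hola", "2020-06-01T23:30:00Z", -7200)])
        f2 = labeled([("hola", "2020-06-01T23:30:00Z", 3600)])
        assert temporal_features(f1, "unknown_treatment")["pct_daytime"] == 100.0
        assert temporal_features(f2, "unknown_treatment")["pct_daytime"] == 0.0

    def test_empty_period_raises(self):
        frame = labeled([("hola", "2020-06-01T12:00:00Z", 0)])
        with pytest.raises(ValueError, match="no tweets"):
            temporal_features(frame, "in_treatment")


class TestLexicalFeatures:
    def test_mean_chars(self):
        frame = labeled(
            [("abcd", "2020-06-01T12:00:00Z", 0), ("ab", "2020-06-01T13:00:00Z", 0)]
        )
        out = lexical_features(frame, "unknown_treatment")
        assert out["mean_chars"] == 3.0

    def test_word_count_excludes_urls_mentions_hashtags(self):
        frame = labeled([("mira esto https://x.y @ana #tag 42", "2020-06-01T12:00:00Z", 0)])
        out = lexical_features(frame, "unknown_treatment")
        assert out["mean_words"] == 3.0  # mira, esto, 42
        assert out["pct_with_link"] == 100.0
        assert out["pct_with_mention"] == 100.0

    def test_emotion_indicator_is_per_tweet(self):
        frame = labeled(
            [
                ("estoy feliz feliz feliz", "2020-06-01T12:00:00Z", 0),
                ("día normal", "2020-06-01T13:00:00Z", 0),
            ]
        )
        out = lexical_features(frame, "unknown_treatment")
        assert out["emo_happiness"] == 50.0
        assert all(out[f"emo_{e}"] == 0.0 for e in ("sadness", "fear", "anger", "disgust", "surprise"))

    def test_negation_counts_tweet_once(self):
        frame = labeled([("no tengo nada", "2020-06-01T12:00:00Z", 0)])
        out = lexical_features(frame, "unknown_treatment")
        assert out["pct_negation"] == 100.0

    def test_polarity_indicators(self):
        frame = labeled(
            [
                ("todo bien hoy", "2020-06-01T12:00:00Z", 0),
                ("qué mal día", "2020-06-01T13:00:00Z", 0),
                ("neutro", "2020-06-01T14:00:00Z", 0),
            ]
        )
        out = lexical_features(frame, "unknown_treatment")
        assert out["pct_positive"] == pytest.approx(100 / 3)
        assert out["pct_negative"] == pytest.approx(100 / 3)

    def test_duplicating_a_word_changes_nothing_duplicating_a_tweet_does(self):
        f1 = labeled([("mal día", "2020-06-01T12:00:00Z", 0), ("bien", "2020-06-01T13:00:00Z", 0)])
        f2 = labeled([("mal mal día", "2020-06-01T12:00:00Z", 0), ("bien", "2020-06-01T13:00:00Z", 0)])
        f3 = labeled(
            [
                ("mal día", "2020-06-01T12:00:00Z", 0),
                ("mal día", "2020-06-01T12:30:00Z", 0),
                ("bien", "2020-06-01T13:00:00Z", 0),
            ]
        )
        k = "pct_negative"
        assert lexical_features(f1, "unknown_treatment")[k] == lexical_features(f2, "unknown_treatment")[k]
        assert lexical_features(f3, "unknown_treatment")[k] > lexical_features(f1, "unknown_treatment")[k]


class TestPosFeatures:
    def test_simple_tally(self):
        frame = labeled([("tomo café café", "2020-06-01T12:00:00Z", 0)])
        out = pos_features(frame, "unknown_treatment")
        assert out["pos_verbs"] == pytest.approx(100 / 3)
        assert out["pos_nouns"] == pytest.approx(200 / 3)
        assert out["pos_pronouns"] == 0.0

    def test_excluded_categories_leave_denominator(self):
        # determiners/adpositions/conjunctions do not enter the denominator
        frame = labeled([("el café de la casa y tomo", "2020-06-01T12:00:00Z", 0)])
        out = pos_features(frame, "unknown_treatment")
        assert out["pos_nouns"] == pytest.approx(200 / 3)
        assert out["pos_verbs"] == pytest.approx(100 / 3)

    def test_pronoun_person_split(self):
        frame = labeled([("yo y tú", "2020-06-01T12:00:00Z", 0)])
        out = pos_features(frame, "unknown_treatment")
        assert out["pron_p1s"] == 50.0 and out["pron_p2s"] == 50.0
        assert out["pron_p3p"] == 0.0

    def test_no_pronouns_gives_missing(self):
        frame = labeled([("café solo", "2020-06-01T12:00:00Z", 0)])
        out = pos_features(frame, "unknown_treatment")
        assert np.isnan(out["pron_p1s"])

    def test_random_tag_multiset_matches_hand_tally(self):
        rng = np.random.default_rng(3)
        vocab = {
            "verb": ["tomo", "dice", "mira"],
            "noun": ["casa", "café", "vida"],
            "pronoun": ["yo", "tú", "ellos"],
            "adverb": ["hoy", "muy"],
            "adjective": ["raro", "grande"],
        }
        words = []
        truth = []
        for _ in range(30):
            cat = rng.choice(list(vocab))
            words.append(str(rng.choice(vocab[cat])))
            truth.append(cat)
        frame = labeled([(" ".join(words), "2020-06-01T12:00:00Z", 0)])
        out = pos_features(frame, "unknown_treatment")
        for cat in vocab:
            assert out[f"pos_{cat}s"] == pytest.approx(100 * truth.count(cat) / 30)


class TestFeaturizerPaths:
    @given(
        st.lists(
            st.lists(
                st.sampled_from(
                    "yo tú tomo café no mal feliz triste muy el de y @ana #x https://t.co/q 42 ! zz".split()
                ),
                min_size=1,
                max_size=12,
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_fast_path_equals_tagger_contract_path(self, tweets):
        rows = [
            (" ".join(words), f"2020-06-01T{10 + i % 12}:00:00Z", 0)
            for i, words in enumerate(tweets)
        ]
        frame = labeled(rows)
        fast = TweetFeaturizer().fit().transform(frame)

        class ContractTagger:
            """Same dictionary, but through the generic tag() contract."""

            def __init__(self):
                self._inner = default_tagger()

            def tag(self, tokens, kinds):
                return self._inner.tag(tokens, kinds)

        generic = TweetFeaturizer(tagger=ContractTagger()).fit().transform(frame)
        pd.testing.assert_frame_equal(fast, generic)

    def test_pos_composition_sums_to_100(self, small_cohort):
        from ssritweets.windows import label_timelines

        frame, events, _ = small_cohort
        lab, _ = label_timelines(frame[~frame["is_retweet"]], events)
        fm = extract_features(lab)
        comp = fm[[f"pos_{p}s" for p in ("verb", "noun", "pronoun", "adverb", "adjective")]]
        # the five reported categories plus the "other" remainder cover 100
        assert (comp.sum(axis=1) <= 100.0 + 1e-9).all()
        pron = fm[[c for c in FEATURE_COLUMNS if c.startswith("pron_")]].dropna()
        assert np.allclose(pron.sum(axis=1), 100.0)

    def test_daytime_and_night_partition(self, small_cohort):
        from ssritweets.windows import label_timelines

        frame, events, _ = small_cohort
        lab, _ = label_timelines(frame[~frame["is_retweet"]], events)
        fm = extract_features(lab)
        assert ((fm["pct_daytime"] >= 0) & (fm["pct_daytime"] <= 100)).all()
        pcts = [c for c in FEATURE_COLUMNS if c.startswith(("pct_", "emo_", "pos_", "pron_"))]
        sub = fm[pcts]
        assert ((sub.isna()) | ((sub >= 0) & (sub <= 100))).all().all()

    def test_emotion_word_share_mode(self):
        frame = labeled([("feliz feliz café café", "2020-06-01T12:00:00Z", 0)])
        out = TweetFeaturizer(emotion_mode="word_share").fit().transform(frame)
        assert out["emo_happiness"].iloc[0] == 50.0
        ind = TweetFeaturizer().fit().transform(frame)
        assert ind["emo_happiness"].iloc[0] == 100.0
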