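"""Per-user, per-period behavioural and linguistic feature battery.

One feature vector summarises everything a user posted inside one treatment
period: posting rhythm on the author's local clock (tweets per day, daytime
share, weekday/weekend rates), tweet length, link/mention usage,
part-of-speech composition, personal-pronoun person/number profile, and
lexicon-driven emotion, negation and sentiment indicators.

Conventions
-----------
* Daytime is the local hour interval [8, 24); night is [0, 8).
* Weekdays are Monday–Friday.
* ``mean_words`` counts tokens of kind word or number; ``mean_chars`` counts
  Unicode codepoints of the raw text, spaces included.
* POS percentages are taken over POS-taggable word tokens excluding
  conjunctions, interjections, punctuation, determiners, adpositions,
  numbers and dates; the catch-all ``other`` category absorbs the remainder
  so the full composition sums to 100.
* Pronoun percentages are over personal pronouns only and sum to 100 when
  any personal pronoun exists; otherwise they are missing.
* Emotion, negation and polarity are tweet-level indicators by default: a
  tweet counts once if it contains at least one lexicon word of the
  category.  A word-share variant (percent of word tokens belonging to the
  category) is available behind ``emotion_mode="word_share"``.
* ``tweets_per_day`` divides by the distinct local calendar days of the
  period's windows clipped to the user's observed timeline span, so quiet
  days count and partially observed windows do not inflate the rate.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .corpus import local_times
from .text import (
    EMOTIONS,
    EXCLUDED_POS,
    POS_TAGS,
    DictionaryTagger,
    WordLexicons,
    default_lexicons,
    default_tagger,
    tokenize,
    _TOKEN_RE,
)
from .windows import WindowLabeler, _label_days

__all__ = [
    "FEATURE_COLUMNS",
    "FEATURE_FAMILIES",
    "TweetFeaturizer",
    "extract_features",
    "temporal_features",
    "lexical_features",
    "pos_features",
]

_POS_REPORT = ("verb", "noun", "pronoun", "adverb", "adjective")
_PRON_SLOTS = ("p1s", "p2s", "p3s", "p1p", "p2p", "p3p")

FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "temporal": (
        "tweets_per_day",
        "pct_daytime",
        "tweets_per_weekday_day",
        "tweets_per_weekend_day",
        "pct_weekday",
    ),
    "length": ("mean_chars", "mean_words"),
    "links_mentions": ("pct_with_link", "pct_with_mention"),
    "pos": tuple(f"pos_{p}s" for p in _POS_REPORT),
    "pronouns": tuple(f"pron_{s}" for s in _PRON_SLOTS),
    "emotions": tuple(f"emo_{e}" for e in EMOTIONS),
    "negation": ("pct_negation",),
    "polarity": ("pct_positive", "pct_negative"),
}

FEATURE_COLUMNS: tuple[str, ...] = tuple(
    c for cols in FEATURE_FAMILIES.values() for c in cols
)

# ---------------------------------------------------------------------------
# packed word-info table: one dict lookup per word token on the fast path
#
# bits 0..3   POS index into POS_TAGS
# bits 4..6   personal-pronoun slot (0 = none, 1..6 = p1s..p3p)
# bits 7..12  emotion category flags (order of EMOTIONS)
# bit  13     negation word
# bit  14     positive word
# bit  15     negative word
# ---------------------------------------------------------------------------

_POS_INDEX = {p: i for i, p in enumerate(POS_TAGS)}
_OTHER_CODE = _POS_INDEX["other"]
_INCLUDED = np.array([p not in EXCLUDED_POS for p in POS_TAGS], dtype=np.int64)
_REPORT_SLOT = np.array(
    [_POS_REPORT.index(p) if p in _POS_REPORT else -1 for p in POS_TAGS],
    dtype=np.int64,
)


def _pron_slot(person, number) -> int:
    if person is None or number is None:
        return 0
    return 1 + (person - 1) + (3 if number == "plural" else 0)


def _build_info(tagger: DictionaryTagger, lexicons: WordLexicons) -> dict[str, int]:
    info: dict[str, int] = {}
    for word, (pos, person, number) in tagger.entries.items():
        info[word] = _POS_INDEX[pos] | (_pron_slot(person, number) << 4)
    for word, emo in lexicons.emotions.items():
        info[word] = info.get(word, _OTHER_CODE) | (1 << (7 + EMOTIONS.index(emo)))
    for word in lexicons.negations:
        info[word] = info.get(word, _OTHER_CODE) | (1 << 13)
    for word, pol in lexicons.sentiment.items():
        bit = 14 if pol == "positive" else 15
        info[word] = info.get(word, _OTHER_CODE) | (1 << bit)
    return info


# per-tweet stats row layout
_N_STATS = 1 + 2 + 1 + 5 + 6 + 6 + 3  # words, url/mention, incl, pos5, pron6, emo6, neg/pos/neg
_COL = {}
for _i, _n in enumerate(
    ["n_words", "has_url", "has_mention", "incl"]
    + [f"pos_{p}" for p in _POS_REPORT]
    + [f"pron_{s}" for s in _PRON_SLOTS]
    + [f"emo_{e}" for e in EMOTIONS]
    + ["neg", "posw", "negw"]
):
    _COL[_n] = _i


def _stats_fast(texts: Sequence[str], info: Mapping[str, int]) -> np.ndarray:
    """Per-tweet stat rows via the packed word-info table."""
    findall = _TOKEN_RE.findall
    get = info.get
    other = _OTHER_CODE
    included = _INCLUDED
    slot = _REPORT_SLOT
    out = np.zeros((len(texts), _N_STATS), dtype=np.int64)
    for i, text in enumerate(texts):
        row = out[i]
        n_words = 0
        for tok in findall(text):
            c0 = tok[0]
            if c0.isalpha() and not (
                tok.startswith("http") and "://" in tok or tok.startswith("www.")
            ):
                n_words += 1
                code = get(tok.lower(), other)
                pos = code & 0xF
                row[3] += included[pos]
                rs = slot[pos]
                if rs >= 0:
                    row[4 + rs] += 1
                high = code >> 4
                if high:
                    ps = high & 0x7
                    if ps:
                        row[8 + ps] += 1  # 9 + (ps-1)
                    flags = code >> 7
                    if flags:
                        for b in range(9):
                            if flags & (1 << b):
                                row[15 + b] += 1
            elif c0 == "@" and len(tok) > 1:
                row[2] = 1
            elif c0.isdigit():
                n_words += 1
            elif tok.startswith("http://") or tok.startswith("https://") or tok.startswith("www."):
                row[1] = 1
        row[0] = n_words
    return out


def _stats_generic(
    texts: Sequence[str], tagger, lexicons: WordLexicons
) -> np.ndarray:
    """Per-tweet stat rows via the full tokenize→tag contract path."""
    out = np.zeros((len(texts), _N_STATS), dtype=np.int64)
    for i, text in enumerate(texts):
        row = out[i]
        tt = tokenize(text)
        tagged = tagger.tag(tt.tokens, tt.kinds)
        for tok, kind, tg in zip(tt.tokens, tt.kinds, tagged):
            if kind in ("word", "number"):
                row[0] += 1
            if kind == "url":
                row[1] = 1
            elif kind == "user_mention":
                row[2] = 1
            if kind != "word":
                continue
            if tg.pos not in EXCLUDED_POS:
                row[3] += 1
            if tg.pos in _POS_REPORT:
                row[4 + _POS_REPORT.index(tg.pos)] += 1
            ps = _pron_slot(tg.pronoun_person, tg.pronoun_number)
            if ps:
                row[9 + ps - 1] += 1
            low = tok.lower()
            emo = lexicons.emotions.get(low)
            if emo is not None:
                row[15 + EMOTIONS.index(emo)] += 1
            if low in lexicons.negations:
                row[21] += 1
            pol = lexicons.sentiment.get(low)
            if pol == "positive":
                row[22] += 1
            elif pol == "negative":
                row[23] += 1
    return out


class TweetFeaturizer(BaseEstimator):
    """Transformer from a labeled tweets frame to the feature matrix.

    ``transform`` expects the labeled frame produced by
    :class:`~ssritweets.windows.WindowLabeler` (all three period labels
    present — the excluded tweets still inform the user's observed span) and
    returns one row per user × analysed period, indexed by
    ``(user_id, period)``, with the columns of :data:`FEATURE_COLUMNS`.

    Parameters
    ----------
    tagger:
        POS tagger honouring the tagger contract; ``None`` uses the packaged
        dictionary tagger (which also enables the fast packed-lookup path).
    lexicons:
        :class:`~ssritweets.text.WordLexicons`; ``None`` uses the packaged
        defaults.
    daytime_start:
        First local hour counted as daytime (daytime is
        ``[daytime_start, 24)``).
    emotion_mode:
        ``"indicator"`` (default, percent of tweets with ≥1 category word)
        or ``"word_share"`` (percent of word tokens in the category).
    labeler:
        Optional fitted :class:`WindowLabeler`; when given, the
        ``tweets_per_day`` denominators are the period's window days clipped
        to the user's observed span.  Without it the fallback denominator is
        the count of distinct days with at least one tweet in the period.
    """

    def __init__(
        self,
        tagger=None,
        lexicons: WordLexicons | None = None,
        daytime_start: int = 8,
        emotion_mode: str = "indicator",
        labeler: WindowLabeler | None = None,
    ):
        self.tagger = tagger
        self.lexicons = lexicons
        self.daytime_start = daytime_start
        self.emotion_mode = emotion_mode
        self.labeler = labeler

    def fit(self, X=None, y=None):
        return self

    def _resolve(self):
        tagger = self.tagger if self.tagger is not None else default_tagger()
        lexicons = self.lexicons if self.lexicons is not None else default_lexicons()
        if self.emotion_mode not in ("indicator", "word_share"):
            raise ValueError("emotion_mode must be 'indicator' or 'word_share'")
        return tagger, lexicons

    def transform(self, labeled: pd.DataFrame) -> pd.DataFrame:
        tagger, lexicons = self._resolve()
        frame = labeled
        local = local_times(frame)
        day = local.to_numpy().astype("datetime64[D]").astype(np.int64)
        analysed = frame["period"].isin(["in_treatment", "unknown_treatment"]).to_numpy()

        sub = frame.loc[analysed]
        texts = sub["text"].tolist()
        if isinstance(tagger, DictionaryTagger):
            stats = _stats_fast(texts, _build_info(tagger, lexicons))
        else:
            stats = _stats_generic(texts, tagger, lexicons)

        hours = local.dt.hour.to_numpy()[analysed]
        wday = ((day + 3) % 7)[analysed]  # 0=Mon .. 6=Sun (epoch day 0 is a Thursday)
        agg = pd.DataFrame(stats, columns=list(_COL))
        agg["user_id"] = sub["user_id"].to_numpy()
        agg["period"] = sub["period"].to_numpy()
        agg["chars"] = sub["text"].str.len().to_numpy()
        agg["daytime"] = (hours >= self.daytime_start).astype(np.int64)
        agg["on_weekday"] = (wday < 5).astype(np.int64)
        agg["n"] = 1

        g = agg.groupby(["user_id", "period"], sort=True).sum(numeric_only=True)

        day_denoms = self._day_denominators(frame, day)
        out = pd.DataFrame(index=g.index)
        n = g["n"].astype(float)
        dd = day_denoms.reindex(g.index)
        out["tweets_per_day"] = n / dd["n_days"]
        out["pct_daytime"] = 100.0 * g["daytime"] / n
        out["tweets_per_weekday_day"] = g["on_weekday"] / dd["n_weekday_days"]
        out["tweets_per_weekend_day"] = (n - g["on_weekday"]) / dd["n_weekend_days"]
        out["pct_weekday"] = 100.0 * g["on_weekday"] / n
        out["mean_chars"] = g["chars"] / n
        out["mean_words"] = g["n_words"] / n
        out["pct_with_link"] = 100.0 * g["has_url"] / n
        out["pct_with_mention"] = 100.0 * g["has_mention"] / n
        incl = g["incl"].astype(float).replace(0.0, np.nan)
        for p in _POS_REPORT:
            out[f"pos_{p}s"] = 100.0 * g[f"pos_{p}"] / incl
        npron = sum(g[f"pron_{s}"] for s in _PRON_SLOTS).astype(float).replace(0.0, np.nan)
        for s in _PRON_SLOTS:
            out[f"pron_{s}"] = 100.0 * g[f"pron_{s}"] / npron
        if self.emotion_mode == "indicator":
            # indicator aggregation needs per-tweet booleans, not word sums
            for j, e in enumerate(EMOTIONS):
                agg[f"_i_emo_{e}"] = (stats[:, 15 + j] > 0).astype(np.int64)
            agg["_i_neg"] = (stats[:, 21] > 0).astype(np.int64)
            agg["_i_posw"] = (stats[:, 22] > 0).astype(np.int64)
            agg["_i_negw"] = (stats[:, 23] > 0).astype(np.int64)
            gi = agg.groupby(["user_id", "period"], sort=True).sum(numeric_only=True)
            for e in EMOTIONS:
                out[f"emo_{e}"] = 100.0 * gi[f"_i_emo_{e}"] / n
            out["pct_negation"] = 100.0 * gi["_i_neg"] / n
            out["pct_positive"] = 100.0 * gi["_i_posw"] / n
            out["pct_negative"] = 100.0 * gi["_i_negw"] / n
        else:
            words = g["n_words"].astype(float).replace(0.0, np.nan)
            for e in EMOTIONS:
                out[f"emo_{e}"] = 100.0 * g[f"emo_{e}"] / words
            out["pct_negation"] = 100.0 * g["neg"] / words
            out["pct_positive"] = 100.0 * g["posw"] / words
            out["pct_negative"] = 100.0 * g["negw"] / words
        return out[list(FEATURE_COLUMNS)]

    def _day_denominators(self, frame: pd.DataFrame, day: np.ndarray) -> pd.DataFrame:
        """Distinct calendar-day counts per (user, period).

        Window days ∩ observed span when a fitted labeler is available,
        otherwise days-with-tweets.  Zero-day cells become NaN so dependent
        rates are missing rather than infinite.
        """
        rows = []
        uids = frame["user_id"].to_numpy()
        labeler = self.labeler
        if labeler is not None:
            cfg = labeler._config()
        for uid in pd.unique(uids):
            mask = uids == uid
            lo, hi = day[mask].min(), day[mask].max()
            user = str(uid)
            if labeler is not None:
                days = np.arange(lo, hi + 1)
                labels = _label_days(
                    days,
                    labeler.anchors_in_.get(user, np.empty(0, dtype=np.int64)),
                    labeler.anchors_washout_.get(user, np.empty(0, dtype=np.int64)),
                    cfg,
                )
            else:
                days = np.unique(day[mask])
                labels = frame.loc[mask, "period"].to_numpy()
                # align: recompute per distinct day using the tweets present
                lab_by_day = {}
                for d, lab in zip(day[mask], labels):
                    lab_by_day[d] = lab
                labels = np.array([lab_by_day[d] for d in days], dtype=object)
            wd = (days + 3) % 7
            for period in ("in_treatment", "unknown_treatment"):
                sel = labels == period
                n_days = int(sel.sum())
                n_wd = int((sel & (wd < 5)).sum())
                n_we = n_days - n_wd
                rows.append((uid, period, n_days or np.nan, n_wd or np.nan, n_we or np.nan))
        return pd.DataFrame(
            rows, columns=["user_id", "period", "n_days", "n_weekday_days", "n_weekend_days"]
        ).set_index(["user_id", "period"])


def extract_features(
    labeled: pd.DataFrame,
    labeler: WindowLabeler | None = None,
    **params,
) -> pd.DataFrame:
    """Functional wrapper over :class:`TweetFeaturizer`."""
    return TweetFeaturizer(labeler=labeler, **params).fit().transform(labeled)


def _single_period(labeled: pd.DataFrame, period: str, **params) -> pd.Series:
    if not (labeled["period"] == period).any():
        raise ValueError(f"no tweets in period {period!r}")
    feats = extract_features(labeled, **params)
    return feats.xs(period, level="period").iloc[0]


def temporal_features(labeled: pd.DataFrame, period: str, **params) -> dict[str, float]:
    """Temporal fields of the feature vector for one user's period."""
    row = _single_period(labeled, period, **params)
    return {k: row[k] for k in FEATURE_FAMILIES["temporal"]}


def lexical_features(labeled: pd.DataFrame, period: str, **params) -> dict[str, float]:
    """Length, link/mention, emotion, negation and polarity fields."""
    keys = (
        FEATURE_FAMILIES["length"]
        + FEATURE_FAMILIES["links_mentions"]
        + FEATURE_FAMILIES["emotions"]
        + FEATURE_FAMILIES["negation"]
        + FEATURE_FAMILIES["polarity"]
    )
    row = _single_period(labeled, period, **params)
    return {k: row[k] for k in keys}


def pos_features(labeled: pd.DataFrame, period: str, **params) -> dict[str, float]:
    """POS-composition and pronoun-person fields."""
    keys = FEATURE_FAMILIES["pos"] + FEATURE_FAMILIES["pronouns"]
    row = _single_period(labeled, period, **params)
    return {k: row[k] for k in keys}
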