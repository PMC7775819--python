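"""Tweet-timeline I/O and basic record handling.

The canonical interchange format is JSON lines (UTF-8, one tweet object per
line).  Canonical field names are ``tweet_id``, ``user_id``,
``created_at_utc``, ``utc_offset_seconds``, ``text`` and ``is_retweet``; a
field map translates raw Twitter-API exports (``id_str``, ``user.id_str``,
``created_at``, ``user.utc_offset``, ``text``, ``retweeted_status``) into
that schema.

In memory the canonical container is a pandas DataFrame with one row per
tweet (the "tweets frame"); :class:`UserTimeline` provides the per-user
record view where that is more convenient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Tweet",
    "UserTimeline",
    "TimelineReadResult",
    "TWITTER_API_FIELD_MAP",
    "CANONICAL_FIELDS",
    "read_timelines",
    "write_timelines",
    "frame_to_timelines",
    "timelines_to_frame",
    "filter_retweets",
    "local_time",
    "local_times",
]

CANONICAL_FIELDS = {
    "tweet_id": "tweet_id",
    "user_id": "user_id",
    "created_at_utc": "created_at_utc",
    "utc_offset_seconds": "utc_offset_seconds",
    "text": "text",
    "is_retweet": "is_retweet",
}

#: Field map for raw Twitter-API JSON exports.  Dotted paths descend into
#: nested objects; ``is_retweet`` maps to presence of ``retweeted_status``.
TWITTER_API_FIELD_MAP = {
    "tweet_id": "id_str",
    "user_id": "user.id_str",
    "created_at_utc": "created_at",
    "utc_offset_seconds": "user.utc_offset",
    "text": "text",
    "is_retweet": "retweeted_status",
}

MAX_UTC_OFFSET = 14 * 3600


@dataclass(frozen=True)
class Tweet:
    """One timeline record."""

    tweet_id: str
    user_id: str
    created_at_utc: datetime
    utc_offset_seconds: int
    text: str
    is_retweet: bool = False

    def local_time(self) -> datetime:
        return self.created_at_utc + timedelta(seconds=self.utc_offset_seconds)


@dataclass
class UserTimeline:
    """A user's tweets, sorted ascending by UTC creation time."""

    user_id: str
    tweets: list[Tweet] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tweets)

    def __iter__(self) -> Iterator[Tweet]:
        return iter(self.tweets)


@dataclass
class TimelineReadResult:
    """Parsed timelines plus a per-line rejects report.

    ``frame`` holds every admitted tweet; ``rejects`` has one row per
    malformed input line (columns ``line_no``, ``reason``).  Rejected lines
    are counted, never silently dropped.
    """

    frame: pd.DataFrame
    rejects: pd.DataFrame

    @property
    def timelines(self) -> list[UserTimeline]:
        return frame_to_timelines(self.frame)

    @property
    def n_users(self) -> int:
        return int(self.frame["user_id"].nunique())


def _get_path(obj: Mapping, path: str):
    cur = obj
    for part in path.split("."):
        if not isinstance(cur, Mapping) or part not in cur:
            raise KeyError(path)
        cur = cur[part]
    return cur


def _parse_timestamp(value) -> datetime:
    if isinstance(value, (int, float)):
        ts = pd.Timestamp(value, unit="s", tz="UTC")
    else:
        ts = pd.Timestamp(value)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    return ts.to_pydatetime()


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tweet_id": pd.Series(dtype=object),
            "user_id": pd.Series(dtype=object),
            "created_at_utc": pd.Series(dtype="datetime64[ns]"),
            "utc_offset_seconds": pd.Series(dtype=np.int64),
            "text": pd.Series(dtype=object),
            "is_retweet": pd.Series(dtype=bool),
        }
    )


def read_timelines(
    path,
    field_map: Mapping[str, str] | None = None,
    default_utc_offset: int | None = 0,
) -> TimelineReadResult:
    """Read a JSONL tweet file into timelines grouped by user.

    Parameters
    ----------
    path:
        JSONL file, one tweet object per line.
    field_map:
        Maps canonical field names to (possibly dotted) source paths.
        Defaults to the canonical names themselves; pass
        :data:`TWITTER_API_FIELD_MAP` for raw API exports.
    default_utc_offset:
        Offset applied when a record carries none (``None`` value in the
        source).  Users with no retrievable offset default to UTC and are
        flagged in the rejects report with reason ``missing_offset_default_utc``
        (the record itself is still admitted).

    Malformed lines (bad JSON, missing required fields, invalid timestamps or
    offsets, empty text) are collected into ``rejects`` with the 1-based line
    number and a reason.
    """
    fmap = dict(CANONICAL_FIELDS)
    if field_map:
        fmap.update(field_map)
    rows = []
    rejects: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError:
                rejects.append((line_no, "invalid_json"))
                continue
            row, note = _extract_record(obj, fmap, default_utc_offset)
            if row is None:
                rejects.append((line_no, note))
                continue
            if note:
                rejects.append((line_no, note))
            rows.append(row)
    if rows:
        frame = pd.DataFrame(
            rows,
            columns=[
                "tweet_id",
                "user_id",
                "created_at_utc",
                "utc_offset_seconds",
                "text",
                "is_retweet",
            ],
        )
        frame["created_at_utc"] = pd.to_datetime(frame["created_at_utc"])
        frame["utc_offset_seconds"] = frame["utc_offset_seconds"].astype(np.int64)
        frame["is_retweet"] = frame["is_retweet"].astype(bool)
        frame = frame.sort_values(
            ["user_id", "created_at_utc"], kind="stable"
        ).reset_index(drop=True)
    else:
        frame = _empty_frame()
    rej = pd.DataFrame(rejects, columns=["line_no", "reason"])
    return TimelineReadResult(frame=frame, rejects=rej)


def _extract_record(obj, fmap, default_utc_offset):
    """Return (row-dict, note) or (None, reason)."""
    if not isinstance(obj, Mapping):
        return None, "not_an_object"
    note = ""
    try:
        raw_ts = _get_path(obj, fmap["created_at_utc"])
    except KeyError:
        return None, "missing_created_at"
    try:
        ts = _parse_timestamp(raw_ts)
    except (ValueError, TypeError):
        return None, "invalid_timestamp"
    try:
        text = _get_path(obj, fmap["text"])
    except KeyError:
        return None, "missing_text"
    if not isinstance(text, str) or not text.strip():
        return None, "empty_text"
    try:
        user_id = str(_get_path(obj, fmap["user_id"]))
    except KeyError:
        return None, "missing_user_id"
    try:
        tweet_id = str(_get_path(obj, fmap["tweet_id"]))
    except KeyError:
        return None, "missing_tweet_id"
    try:
        offset = _get_path(obj, fmap["utc_offset_seconds"])
    except KeyError:
        offset = None
    if offset is None:
        if default_utc_offset is None:
            return None, "missing_offset"
        offset = default_utc_offset
        note = "missing_offset_default_utc"
    try:
        offset = int(offset)
    except (TypeError, ValueError):
        return None, "invalid_offset"
    if not -MAX_UTC_OFFSET <= offset <= MAX_UTC_OFFSET:
        return None, "offset_out_of_range"
    # is_retweet: boolean field, or presence of a nested object (API style)
    try:
        rt = _get_path(obj, fmap["is_retweet"])
        is_retweet = bool(rt) if not isinstance(rt, Mapping) else True
    except KeyError:
        is_retweet = False
    return (
        {
            "tweet_id": tweet_id,
            "user_id": user_id,
            "created_at_utc": ts,
            "utc_offset_seconds": offset,
            "text": text,
            "is_retweet": is_retweet,
        },
        note,
    )


def write_timelines(frame_or_timelines, path) -> None:
    """Write tweets to canonical JSONL (round-trips with read_timelines)."""
    frame = (
        frame_or_timelines
        if isinstance(frame_or_timelines, pd.DataFrame)
        else timelines_to_frame(frame_or_timelines)
    )
    with open(path, "w", encoding="utf-8") as fh:
        for row in frame.itertuples(index=False):
            obj = {
                "tweet_id": row.tweet_id,
                "user_id": row.user_id,
                "created_at_utc": pd.Timestamp(row.created_at_utc).strftime(
                    "%Y-%m-%dT%H:%M:%SZ"
                ),
                "utc_offset_seconds": int(row.utc_offset_seconds),
                "text": row.text,
                "is_retweet": bool(row.is_retweet),
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def frame_to_timelines(frame: pd.DataFrame) -> list[UserTimeline]:
    out = []
    for user_id, grp in frame.groupby("user_id", sort=True):
        tweets = [
            Tweet(
                tweet_id=r.tweet_id,
                user_id=r.user_id,
                created_at_utc=pd.Timestamp(r.created_at_utc).to_pydatetime(),
                utc_offset_seconds=int(r.utc_offset_seconds),
                text=r.text,
                is_retweet=bool(r.is_retweet),
            )
            for r in grp.itertuples(index=False)
        ]
        out.append(UserTimeline(user_id=str(user_id), tweets=tweets))
    return out


def timelines_to_frame(timelines: Iterable[UserTimeline]) -> pd.DataFrame:
    rows = []
    for tl in timelines:
        for t in tl.tweets:
            rows.append(
                (
                    t.tweet_id,
                    t.user_id,
                    t.created_at_utc,
                    t.utc_offset_seconds,
                    t.text,
                    t.is_retweet,
                )
            )
    if not rows:
        return _empty_frame()
    frame = pd.DataFrame(
        rows,
        columns=[
            "tweet_id",
            "user_id",
            "created_at_utc",
            "utc_offset_seconds",
            "text",
            "is_retweet",
        ],
    )
    frame["created_at_utc"] = pd.to_datetime(frame["created_at_utc"])
    return frame


def filter_retweets(
    data,
    rt_prefix_rule: bool = True,
):
    """Drop retweets, preserving order.

    A tweet is a retweet when its ``is_retweet`` flag is set or — under the
    default prefix rule — when its text starts with ``"RT @"`` after leading
    whitespace is stripped (old-style manual retweets carry no flag).

    Accepts either a tweets frame (returns ``(kept_frame, n_removed)``) or a
    :class:`UserTimeline` (returns the filtered timeline; removed count is
    ``len(input) - len(output)``).
    """
    if isinstance(data, UserTimeline):
        kept = [t for t in data.tweets if not _is_retweet(t.is_retweet, t.text, rt_prefix_rule)]
        return UserTimeline(user_id=data.user_id, tweets=kept)
    frame = data
    mask = frame["is_retweet"].to_numpy(dtype=bool)
    if rt_prefix_rule and len(frame):
        prefix = frame["text"].str.lstrip().str.startswith("RT @").to_numpy(dtype=bool)
        mask = mask | prefix
    kept = frame.loc[~mask].reset_index(drop=True)
    return kept, int(mask.sum())


def _is_retweet(flag: bool, text: str, rt_prefix_rule: bool) -> bool:
    return bool(flag) or (rt_prefix_rule and text.lstrip().startswith("RT @"))


def local_time(tweet: Tweet) -> datetime:
    """The tweet's timestamp on the author's local clock.

    All temporal features (hour, calendar date, weekday) are derived from
    this value only; the tweet hours are adjusted by the user's time zone.
    """
    return tweet.local_time()


def local_times(frame: pd.DataFrame) -> pd.Series:
    """Vectorized local timestamps (tz-naive) for a tweets frame."""
    ts = frame["created_at_utc"]
    if isinstance(ts.dtype, pd.DatetimeTZDtype):
        ts = ts.dt.tz_convert("UTC").dt.tz_localize(None)
    return ts + pd.to_timedelta(frame["utc_offset_seconds"], unit="s")
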