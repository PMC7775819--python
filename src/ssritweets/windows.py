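"""Exposure-window classification of tweets.

Every non-retweet tweet is classified, on the author's local calendar, into
one of three mutually exclusive periods relative to the user's drug-mention
anchor dates:

* ``in_treatment`` — within the 30 days after an intake-mention tweet (the
  mention day itself counts as day 0 and is in-treatment);
* ``unknown_treatment`` — strictly more than 90 days before or after *every*
  mention;
* ``excluded`` — everything in between (the washout zone).

The anchor sets are configurable: by default the in-treatment windows open
only at intake-confirmed mentions while the washout distance is measured
from *all* mentions, so a casual mention still blocks the unknown period.
Day arithmetic is on local calendar dates, never on raw timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .corpus import UserTimeline, local_times, timelines_to_frame

__all__ = [
    "PERIODS",
    "WindowConfig",
    "WindowLabeler",
    "label_tweet",
    "label_timelines",
    "select_users",
    "threshold_sweep",
]

PERIODS = ("in_treatment", "unknown_treatment", "excluded")


@dataclass(frozen=True)
class WindowConfig:
    """Window-rule parameters.

    ``in_treatment_days`` is the length of the exposure window opened by an
    anchor mention (days after the anchor; the anchor day itself counts);
    ``washout_days`` the distance beyond which treatment status is unknown;
    ``min_tweets_per_dataset`` the cohort-inclusion floor applied to both
    periods.
    """

    in_treatment_days: int = 30
    washout_days: int = 90
    min_tweets_per_dataset: int = 30
    in_treatment_anchor: str = "intake_confirmed_only"  # or "any_mention"
    washout_anchor: str = "any_mention"  # or "intake_confirmed_only"

    def __post_init__(self):
        if not 0 < self.in_treatment_days < self.washout_days:
            raise ValueError("need 0 < in_treatment_days < washout_days")
        if self.min_tweets_per_dataset < 1:
            raise ValueError("min_tweets_per_dataset must be >= 1")
        for fld in ("in_treatment_anchor", "washout_anchor"):
            if getattr(self, fld) not in ("intake_confirmed_only", "any_mention"):
                raise ValueError(f"bad {fld}")


def label_tweet(t_local_date, anchors_in, anchors_washout, cfg: WindowConfig) -> str:
    """Classify a single local calendar date against anchor date sets."""
    if not anchors_in and not anchors_washout:
        raise ValueError("user has no anchors; should not enter labeling")
    t = pd.Timestamp(t_local_date).normalize()
    for m in anchors_in:
        d = (t - pd.Timestamp(m).normalize()).days
        if 0 <= d <= cfg.in_treatment_days:
            return "in_treatment"
    if all(
        abs((t - pd.Timestamp(m).normalize()).days) > cfg.washout_days
        for m in anchors_washout
    ):
        return "unknown_treatment"
    return "excluded"


def _anchor_dates(events: pd.DataFrame, confirmed_only: bool) -> dict[str, np.ndarray]:
    ev = events
    if confirmed_only:
        ev = ev[ev["intake_confirmed"].astype(bool)]
    when = pd.to_datetime(ev["when_utc"])
    if isinstance(when.dtype, pd.DatetimeTZDtype):
        when = when.dt.tz_convert("UTC").dt.tz_localize(None)
    local = when + pd.to_timedelta(ev.get("utc_offset_seconds", 0), unit="s")
    days = local.to_numpy().astype("datetime64[D]").astype(np.int64)
    out: dict[str, np.ndarray] = {}
    for uid, grp in pd.DataFrame({"user_id": ev["user_id"], "day": days}).groupby(
        "user_id", sort=False
    ):
        out[str(uid)] = np.unique(grp["day"].to_numpy())
    return out


class WindowLabeler(BaseEstimator):
    """Transformer labeling tweets into treatment periods.

    ``fit`` consumes a mention-events frame (columns ``user_id``,
    ``when_utc``, ``intake_confirmed``; optional ``utc_offset_seconds`` to
    place the anchor on the author's local calendar) and builds the per-user
    anchor date sets.  ``transform`` takes a retweet-free tweets frame and
    returns it with a ``period`` column appended.  Users with no anchors are
    dropped with reason ``no_mention``, recorded in ``dropped_users_``.
    """

    def __init__(
        self,
        in_treatment_days: int = 30,
        washout_days: int = 90,
        min_tweets_per_dataset: int = 30,
        in_treatment_anchor: str = "intake_confirmed_only",
        washout_anchor: str = "any_mention",
    ):
        self.in_treatment_days = in_treatment_days
        self.washout_days = washout_days
        self.min_tweets_per_dataset = min_tweets_per_dataset
        self.in_treatment_anchor = in_treatment_anchor
        self.washout_anchor = washout_anchor

    def _config(self) -> WindowConfig:
        return WindowConfig(
            in_treatment_days=self.in_treatment_days,
            washout_days=self.washout_days,
            min_tweets_per_dataset=self.min_tweets_per_dataset,
            in_treatment_anchor=self.in_treatment_anchor,
            washout_anchor=self.washout_anchor,
        )

    def fit(self, mention_events: pd.DataFrame, y=None):
        cfg = self._config()
        if mention_events.empty:
            raise ValueError("no mention events")
        self.anchors_in_ = _anchor_dates(
            mention_events, cfg.in_treatment_anchor == "intake_confirmed_only"
        )
        self.anchors_washout_ = _anchor_dates(
            mention_events, cfg.washout_anchor == "intake_confirmed_only"
        )
        return self

    def transform(self, tweets: pd.DataFrame) -> pd.DataFrame:
        """Append a ``period`` column; drop users without anchors."""
        cfg = self._config()
        local_days = (
            local_times(tweets).to_numpy().astype("datetime64[D]").astype(np.int64)
        )
        uid = tweets["user_id"].to_numpy()
        labels = np.empty(len(tweets), dtype=object)
        keep = np.ones(len(tweets), dtype=bool)
        dropped: list[tuple[str, str]] = []
        order = np.argsort(uid, kind="stable")
        bounds = np.flatnonzero(
            np.r_[True, uid[order][1:] != uid[order][:-1], True]
        )
        for s, e in zip(bounds[:-1], bounds[1:]):
            idx = order[s:e]
            user = str(uid[idx[0]])
            a_in = self.anchors_in_.get(user, np.empty(0, dtype=np.int64))
            a_wo = self.anchors_washout_.get(user, np.empty(0, dtype=np.int64))
            if a_in.size == 0 and a_wo.size == 0:
                keep[idx] = False
                dropped.append((user, "no_mention"))
                continue
            labels[idx] = _label_days(local_days[idx], a_in, a_wo, cfg)
        self.dropped_users_ = pd.DataFrame(dropped, columns=["user_id", "reason"])
        out = tweets.loc[keep].copy()
        out["period"] = labels[keep]
        return out

    def fit_transform(self, mention_events, tweets):  # convenience
        return self.fit(mention_events).transform(tweets)


def _label_days(
    days: np.ndarray, a_in: np.ndarray, a_wo: np.ndarray, cfg: WindowConfig
) -> np.ndarray:
    """Vectorized window rule on integer day numbers."""
    if a_in.size:
        d = days[:, None] - a_in[None, :]
        in_treat = ((d >= 0) & (d <= cfg.in_treatment_days)).any(axis=1)
    else:
        in_treat = np.zeros(days.size, dtype=bool)
    if a_wo.size:
        far = (np.abs(days[:, None] - a_wo[None, :]) > cfg.washout_days).all(axis=1)
    else:
        far = np.ones(days.size, dtype=bool)
    out = np.where(in_treat, "in_treatment", np.where(far, "unknown_treatment", "excluded"))
    return out.astype(object)


def label_timelines(
    timelines,
    mention_events: pd.DataFrame,
    cfg: WindowConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper over :class:`WindowLabeler`.

    Accepts a tweets frame or an iterable of :class:`UserTimeline`; returns
    ``(labeled_frame, dropped_users)``.
    """
    cfg = cfg or WindowConfig()
    if not isinstance(timelines, pd.DataFrame):
        timelines = timelines_to_frame(timelines)
    labeler = WindowLabeler(
        in_treatment_days=cfg.in_treatment_days,
        washout_days=cfg.washout_days,
        min_tweets_per_dataset=cfg.min_tweets_per_dataset,
        in_treatment_anchor=cfg.in_treatment_anchor,
        washout_anchor=cfg.washout_anchor,
    )
    labeled = labeler.fit(mention_events).transform(timelines)
    return labeled, labeler.dropped_users_


def period_counts(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per-user tweet counts per period (columns = the three periods)."""
    counts = (
        labeled.groupby(["user_id", "period"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(PERIODS), fill_value=0)
    )
    counts.columns.name = None
    return counts


def select_users(labeled: pd.DataFrame, cfg: WindowConfig | None = None) -> list[str]:
    """Users with at least the minimum tweet count in both periods.

    The boundary is inclusive: a user with exactly the minimum in each
    dataset is included.
    """
    cfg = cfg or WindowConfig()
    counts = period_counts(labeled)
    ok = (counts["in_treatment"] >= cfg.min_tweets_per_dataset) & (
        counts["unknown_treatment"] >= cfg.min_tweets_per_dataset
    )
    return [str(u) for u in counts.index[ok]]


def threshold_sweep(
    labeled: pd.DataFrame, thresholds: Sequence[int] = (10, 30, 60, 100)
) -> pd.DataFrame:
    """Included-user count for each candidate minimum-tweets threshold."""
    counts = period_counts(labeled)
    rows = []
    for thr in thresholds:
        ok = (counts["in_treatment"] >= thr) & (counts["unknown_treatment"] >= thr)
        rows.append((thr, int(ok.sum())))
    return pd.DataFrame(rows, columns=["min_tweets", "included_users"])
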