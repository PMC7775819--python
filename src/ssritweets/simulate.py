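"""Synthetic tweet-timeline cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every pipeline stage is testable without any real Twitter data:

* per-user Poisson tweet streams whose daily rate depends on the treatment
  period (higher while in treatment), with separate weekday/weekend rates;
* circadian placement (daytime = local hours [8, 24)) and per-user fixed
  UTC offsets;
* synthetic token-soup tweet text whose token mixture plants, with
  configured per-user probabilities, part-of-speech dictionary words,
  personal pronouns by person/number, emotion/sentiment/negation lexicon
  words, links and @user mentions;
* drug-name mentions embedded in the tweets of configured anchor days,
  emitted as intake-confirmed mention events;
* optional retweet traffic (flagged, filtered by the pipeline).

Between-user heterogeneity: each user carries latent per-period parameters
(tweet rate, daytime probability, word count, indicator probabilities, POS
and pronoun mixtures) drawn from distributions whose per-period mean and SD
are configurable, with a Gaussian-copula correlation linking the user's two
periods.  The correlation is what makes the SD of paired differences — and
hence the paired t test — meaningful.  Default means/SDs/correlations are
calibrated so the planted per-user differences match the study conditions
the package reproduces (e.g. tweet rates 11.44 vs 9.07 per day with an SD
of differences of 9.72).

Text is deliberately synthetic: all downstream features depend only on
token and lexicon structure, which the token factory controls exactly.
Everything is deterministic given one seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .lexicon import DrugLexicon, default_lexicon
from .text import EMOTIONS, WordLexicons, default_lexicons, default_tagger
from .windows import WindowConfig, _label_days

__all__ = ["PairedLatent", "CohortConfig", "GroundTruth", "generate_cohort", "validate_against_windows"]

_PRON_SLOTS = ("p1s", "p2s", "p3s", "p1p", "p2p", "p3p")
_POS_CATS = ("verb", "noun", "pronoun", "adverb", "adjective", "other")


def _rho(s_in: float, s_unk: float, sd_diff: float) -> float:
    """Cross-period correlation implied by marginal SDs and SD of differences."""
    return (s_in**2 + s_unk**2 - sd_diff**2) / (2.0 * s_in * s_unk)


@dataclass(frozen=True)
class PairedLatent:
    """A user-level latent parameter with per-period mean/SD and correlation.

    ``dist`` chooses the marginal family: ``gamma`` for positive rates and
    counts, ``beta`` for probabilities and shares.  The two periods are
    coupled through a Gaussian copula with correlation ``corr``.
    """

    mean_in: float
    mean_unk: float
    sd_in: float
    sd_unk: float
    corr: float
    dist: str = "beta"

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """(n, 2) array of latent values, column 0 = in-treatment."""
        cov = np.array([[1.0, self.corr], [self.corr, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
        u = sps.norm.cdf(z)
        out = np.empty((n, 2))
        for j, (m, s) in enumerate(
            [(self.mean_in, self.sd_in), (self.mean_unk, self.sd_unk)]
        ):
            if s == 0:
                out[:, j] = m
            elif self.dist == "gamma":
                shape = (m / s) ** 2
                out[:, j] = sps.gamma.ppf(u[:, j], a=shape, scale=s**2 / m)
            elif self.dist == "beta":
                v = s**2
                vmax = m * (1.0 - m)
                if v >= vmax:
                    raise ValueError(f"beta sd {s} infeasible for mean {m}")
                k = vmax / v - 1.0
                out[:, j] = sps.beta.ppf(u[:, j], a=m * k, b=(1.0 - m) * k)
            else:
                raise ValueError(f"unknown dist {self.dist!r}")
        return out

    def nulled(self) -> "PairedLatent":
        """Same marginal for both periods (no planted effect)."""
        return dataclasses.replace(
            self, mean_in=self.mean_unk, sd_in=self.sd_unk
        )


def _beta(mi, mu, si, su, sd_diff=None, corr=None):
    return PairedLatent(mi, mu, si, su, corr if corr is not None else _rho(si, su, sd_diff), "beta")


def _default_latents() -> dict[str, PairedLatent]:
    lat: dict[str, PairedLatent] = {}
    # posting rate (tweets/day) and daytime share: calibrated from the
    # per-period means/SDs and the SD of paired differences
    lat["rate"] = PairedLatent(11.44, 9.07, 10.05, 7.21, _rho(10.05, 7.21, 9.72), "gamma")
    lat["p_daytime"] = _beta(0.643, 0.6178, 0.1483, 0.1369, sd_diff=0.1181)
    lat["p_weekday"] = _beta(0.7595, 0.7440, 0.0917, 0.0531, sd_diff=0.089)
    lat["words"] = PairedLatent(15.68, 15.09, 5.75, 5.20, _rho(5.75, 5.20, 3.54), "gamma")
    lat["p_link"] = _beta(0.2310, 0.2327, 0.1616, 0.1529, sd_diff=0.1094)
    lat["p_mention"] = _beta(0.4579, 0.4352, 0.2477, 0.2471, sd_diff=0.1213)
    lat["p_negation"] = _beta(0.2766, 0.2659, 0.1054, 0.0987, sd_diff=0.0699)
    lat["p_positive"] = _beta(0.1513, 0.1450, 0.0656, 0.0543, sd_diff=0.0522)
    lat["p_negative"] = _beta(0.0797, 0.0754, 0.0440, 0.0352, sd_diff=0.0358)
    # emotion indicator probabilities: only the SD of differences is known,
    # so marginal SD = sd_diff with correlation 0.5 (reproduces sd_diff)
    emo = {
        "happiness": (0.2693, 0.2594, 0.0582),
        "sadness": (0.1001, 0.0976, 0.0420),
        "fear": (0.0320, 0.0302, 0.0194),
        "anger": (0.0552, 0.0520, 0.0271),
        "disgust": (0.0311, 0.0306, 0.0197),
        "surprise": (0.0559, 0.0506, 0.0242),
    }
    for e, (mi, mu, sd) in emo.items():
        lat[f"p_emo_{e}"] = _beta(mi, mu, sd, sd, corr=0.5)
    # POS composition of the POS-percentage denominator (same convention)
    pos = {
        "verb": (0.1850, 0.1820, 0.0128),
        "noun": (0.1950, 0.1994, 0.0257),
        "pronoun": (0.0919, 0.0893, 0.0133),
        "adverb": (0.0642, 0.0636, 0.0084),
        "adjective": (0.0605, 0.0621, 0.0095),
    }
    for c, (mi, mu, sd) in pos.items():
        lat[f"pos_{c}"] = _beta(mi, mu, sd, sd, corr=0.5)
    # personal pronoun person/number shares (normalized per draw)
    pron = {
        "p1s": (0.4950, 0.4780, 0.0868),
        "p2s": (0.1477, 0.1607, 0.0617),
        "p3s": (0.2213, 0.2286, 0.0579),
        "p1p": (0.0344, 0.0343, 0.0343),
        "p2p": (0.0100, 0.0100, 0.0122),
        "p3p": (0.0560, 0.0539, 0.0368),
    }
    for s, (mi, mu, sd) in pron.items():
        lat[f"pron_{s}"] = _beta(mi, mu, sd, sd, corr=0.5)
    return lat


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Scalar conveniences (``base_rate_per_day`` …) mirror the headline
    conditions; the full per-feature calibration lives in ``latents``.
    Spans are in months (30.44 days); ``months_span_sd = 0`` makes every
    user's observation span deterministic.
    """

    n_users: int = 187
    months_span: float = 28.2
    months_span_sd: float = 24.7
    min_span_days: int = 130
    anchors_per_user: int = 1
    function_word_share: float = 0.2
    retweet_fraction: float = 0.2788
    utc_offsets: tuple[int, ...] = (3600, 7200, -10800, -14400, -18000)
    start_date: str = "2017-01-06"
    latents: dict[str, PairedLatent] = field(default_factory=_default_latents)
    drug_name: str = "fluoxetina"
    seed: int = 0

    @property
    def base_rate_per_day(self) -> float:
        return self.latents["rate"].mean_unk

    @property
    def in_treatment_rate_per_day(self) -> float:
        return self.latents["rate"].mean_in

    def nulled(self) -> "CohortConfig":
        """Copy with every planted effect removed (both periods identical)."""
        return dataclasses.replace(
            self, latents={k: v.nulled() for k, v in self.latents.items()}
        )

    @classmethod
    def compact(cls, n_users: int = 187, **overrides) -> "CohortConfig":
        """Replicate-study conditions: calibrated effects at desk scale.

        Every planted effect keeps its default calibration; only the
        observation geometry shrinks — a fixed ~4.2-month span per user
        (31 in-treatment days, a washout zone, and >=35 unknown days) and no
        retweet traffic — so that many replicate cohorts fit a single-CPU
        budget.
        """
        base = dict(
            n_users=n_users,
            months_span=4.2,
            months_span_sd=0.0,
            retweet_fraction=0.0,
        )
        base.update(overrides)
        return dataclasses.replace(cls(), **base)

    @classmethod
    def compact_null(cls, n_users: int = 50, rate: float = 3.0, rate_sd: float = 2.0) -> "CohortConfig":
        """Null-calibration conditions: no planted effect anywhere.

        A quieter posting rate keeps replicate cohorts cheap; the type-I
        error of the paired t test does not depend on tweet volume once the
        minimum-tweets inclusion rule is satisfiable.
        """
        return cls.compact(n_users=n_users).nulled().with_latent(
            "rate", mean_in=rate, mean_unk=rate, sd_in=rate_sd, sd_unk=rate_sd
        )

    def with_latent(self, name: str, **changes) -> "CohortConfig":
        lat = dict(self.latents)
        lat[name] = dataclasses.replace(lat[name], **changes)
        return dataclasses.replace(self, latents=lat)

    def to_yaml(self, path) -> None:
        obj = dataclasses.asdict(self)
        obj["utc_offsets"] = list(self.utc_offsets)
        obj["latents"] = {k: dataclasses.asdict(v) for k, v in self.latents.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(obj, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            obj = yaml.safe_load(fh)
        obj["latents"] = {k: PairedLatent(**v) for k, v in obj.get("latents", {}).items()}
        if not obj["latents"]:
            obj.pop("latents")
        obj["utc_offsets"] = tuple(obj.get("utc_offsets", cls.utc_offsets))
        return cls(**obj)

    def validate(self) -> None:
        if self.n_users < 1 or self.anchors_per_user < 1:
            raise ValueError("n_users and anchors_per_user must be >= 1")
        if not 0 <= self.retweet_fraction < 1:
            raise ValueError("retweet_fraction must be in [0, 1)")
        if not 0 <= self.function_word_share < 1:
            raise ValueError("function_word_share must be in [0, 1)")
        for name, lat in self.latents.items():
            if not -1 < lat.corr < 1:
                raise ValueError(f"latent {name}: correlation out of range")
            if lat.dist == "beta" and not (
                0 < lat.mean_in < 1 and 0 < lat.mean_unk < 1
            ):
                raise ValueError(f"latent {name}: beta mean out of (0, 1)")


@dataclass
class GroundTruth:
    """What the generator planted, for validation against the pipeline."""

    user_ids: list[str]
    anchor_days: dict[str, np.ndarray]  # local epoch-day numbers
    planted_period: pd.Series  # indexed by tweet_id (non-retweet tweets)
    latents: dict[str, np.ndarray]  # feature -> (n_users, 2), col 0 in-treatment


def _word_pools(tagger, lexicons: WordLexicons, drug_lexicon: DrugLexicon):
    """Token pools per category, excluding special-lexicon and drug words."""
    special = (
        set(lexicons.emotions)
        | set(lexicons.sentiment)
        | set(lexicons.negations)
        | {n.lower() for n in (e[0] for e in drug_lexicon.entries)}
    )
    by_cat: dict[str, list[str]] = {c: [] for c in _POS_CATS}
    func: list[str] = []
    pron_by_slot: dict[str, list[str]] = {s: [] for s in _PRON_SLOTS}
    for word, (pos, person, number) in tagger.entries.items():
        if word in special:
            continue
        if pos == "pronoun":
            if person is not None:
                slot = f"p{person}{'p' if number == 'plural' else 's'}"
                pron_by_slot[slot].append(word)
                by_cat["pronoun"].append(word)
        elif pos in by_cat:
            by_cat[pos].append(word)
        elif pos in ("determiner", "adposition", "conjunction"):
            func.append(word)
    pools = {c: np.array(sorted(ws), dtype=object) for c, ws in by_cat.items()}
    pools["function"] = np.array(sorted(func), dtype=object)
    slots = {s: np.array(sorted(ws), dtype=object) for s, ws in pron_by_slot.items()}
    lex_pools = {
        f"emo_{e}": np.array(sorted(w for w, c in lexicons.emotions.items() if c == e), dtype=object)
        for e in EMOTIONS
    }
    lex_pools["negation"] = np.array(sorted(lexicons.negations), dtype=object)
    lex_pools["positive"] = np.array(
        sorted(w for w, c in lexicons.sentiment.items() if c == "positive"), dtype=object
    )
    lex_pools["negative"] = np.array(
        sorted(w for w, c in lexicons.sentiment.items() if c == "negative"), dtype=object
    )
    return pools, slots, lex_pools


_IND_KEYS = [f"emo_{e}" for e in EMOTIONS] + ["negation", "positive", "negative"]
_IND_PARAM = {f"emo_{e}": f"p_emo_{e}" for e in EMOTIONS}
_IND_PARAM.update(negation="p_negation", positive="p_positive", negative="p_negative")


def generate_cohort(
    cfg: CohortConfig,
    window_cfg: WindowConfig | None = None,
    seed: int | None = None,
    tagger=None,
    lexicons: WordLexicons | None = None,
    drug_lexicon: DrugLexicon | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (tweets frame, mention events frame, ground truth).

    The tweets frame is in the canonical corpus schema, sorted by user and
    time; mention events carry ``intake_confirmed = True`` anchors.  The
    period planted for each tweet follows the same window rule the labeling
    stage applies, evaluated on the planted anchor days.
    """
    cfg.validate()
    wcfg = window_cfg or WindowConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    tagger = tagger or default_tagger()
    lexicons = lexicons or default_lexicons()
    drug_lexicon = drug_lexicon or default_lexicon()
    pools, pron_pools, lex_pools = _word_pools(tagger, lexicons, drug_lexicon)

    n = cfg.n_users
    user_ids = [f"u{i:05d}" for i in range(n)]
    lat = {k: v.draw(rng, n) for k, v in cfg.latents.items()}

    # spans (days) and anchor placement on the user's local calendar
    m_days = cfg.months_span * 30.44
    if cfg.months_span_sd > 0:
        s_days = cfg.months_span_sd * 30.44
        shape = (m_days / s_days) ** 2
        spans = rng.gamma(shape, s_days**2 / m_days, size=n)
    else:
        spans = np.full(n, m_days)
    spans = np.maximum(spans, cfg.min_span_days).astype(np.int64)
    start0 = np.datetime64(cfg.start_date, "D").astype(np.int64)
    starts = start0 + rng.integers(0, 7, size=n)  # stagger weekday alignment
    offsets = rng.choice(np.array(cfg.utc_offsets, dtype=np.int64), size=n)

    reach = wcfg.washout_days + 36  # room for the window plus >=35 unknown days
    anchor_days: dict[str, np.ndarray] = {}
    for i, uid in enumerate(user_ids):
        hi = max(1, spans[i] - reach)
        a = starts[i] + rng.integers(0, hi, size=cfg.anchors_per_user)
        anchor_days[uid] = np.unique(a)

    # normalized pronoun mixes per user x period
    pron_raw = np.stack([lat[f"pron_{s}"] for s in _PRON_SLOTS], axis=2)  # (n,2,6)
    pron_mix = pron_raw / pron_raw.sum(axis=2, keepdims=True)
    pos_raw = np.stack(
        [lat[f"pos_{c}"] for c in _POS_CATS if c != "other"], axis=2
    )  # (n,2,5)
    pos_other = np.clip(1.0 - pos_raw.sum(axis=2, keepdims=True), 0.05, None)
    pos_mix = np.concatenate([pos_raw, pos_other], axis=2)
    pos_mix /= pos_mix.sum(axis=2, keepdims=True)

    frames = []
    planted = []
    events = []
    rt_factor = cfg.retweet_fraction / (1.0 - cfg.retweet_fraction)
    for i, uid in enumerate(user_ids):
        days = np.arange(starts[i], starts[i] + spans[i])
        labels = _label_days(days - starts[i], anchor_days[uid] - starts[i],
                             anchor_days[uid] - starts[i], wcfg)
        pcol = np.where(labels == "in_treatment", 0, 1)  # excluded uses unknown params
        wd = (days + 3) % 7
        p_wd = lat["p_weekday"][i, pcol]
        rate = lat["rate"][i, pcol] * np.where(wd < 5, 1.4 * p_wd, 3.5 * (1.0 - p_wd))
        counts = rng.poisson(rate)
        is_anchor_day = np.isin(days, anchor_days[uid])
        counts = np.where(is_anchor_day, np.maximum(counts, 1), counts)

        nt = int(counts.sum())
        t_day = np.repeat(days, counts)
        t_per = np.repeat(pcol, counts)
        t_label = np.repeat(labels, counts)

        # word budgets and planted indicator words
        w_mean = np.maximum(lat["words"][i, t_per], 1.05)
        W = 1 + rng.poisson(w_mean - 1.0)
        ind = {
            k: rng.random(nt) < lat[_IND_PARAM[k]][i, t_per] for k in _IND_KEYS
        }
        L = np.sum([v for v in ind.values()], axis=0)
        W = np.maximum(W, L + 1)
        F = rng.binomial(W - L, cfg.function_word_share)
        C = W - L - F

        texts = _assemble_texts(
            rng, i, t_per, C, F, ind, pos_mix, pron_mix, pools, pron_pools, lex_pools,
            lat, nt,
        )

        # drug mention on the first tweet of each anchor day
        first_of_day = np.r_[True, t_day[1:] != t_day[:-1]]
        anchor_rows = np.flatnonzero(first_of_day & np.isin(t_day, anchor_days[uid]))
        for r in anchor_rows:
            texts[r] = texts[r] + " " + cfg.drug_name

        daytime = rng.random(nt) < lat["p_daytime"][i, t_per]
        secs = np.where(
            daytime,
            8 * 3600 + (rng.random(nt) * 16 * 3600),
            rng.random(nt) * 8 * 3600,
        ).astype(np.int64)
        local_s = t_day * 86400 + secs
        utc_s = local_s - offsets[i]

        # retweets: flagged extra traffic, filtered out by the pipeline
        if cfg.retweet_fraction > 0:
            rt_counts = rng.poisson(rate * rt_factor)
            nrt = int(rt_counts.sum())
        else:
            rt_counts = None
            nrt = 0
        if nrt:
            rt_day = np.repeat(days, rt_counts)
            rt_secs = (rng.random(nrt) * 86400).astype(np.int64)
            rt_utc = rt_day * 86400 + rt_secs - offsets[i]
            all_utc = np.r_[utc_s, rt_utc]
            all_text = texts + ["RT @amiga: qué día"] * nrt
            all_rt = np.r_[np.zeros(nt, dtype=bool), np.ones(nrt, dtype=bool)]
            all_label = np.r_[t_label, np.full(nrt, "retweet", dtype=object)]
        else:
            all_utc, all_text, all_rt, all_label = utc_s, texts, np.zeros(nt, dtype=bool), t_label
        order = np.argsort(all_utc, kind="stable")
        uf = pd.DataFrame(
            {
                "user_id": uid,
                "created_at_utc": all_utc[order].astype("datetime64[s]").astype("datetime64[ns]"),
                "utc_offset_seconds": int(offsets[i]),
                "text": [all_text[j] for j in order],
                "is_retweet": all_rt[order],
            }
        )
        frames.append(uf)
        planted.append(all_label[order])

        anchor_utc = utc_s[anchor_rows]
        for ts in np.sort(anchor_utc):
            events.append(
                (uid, pd.Timestamp(np.int64(ts), unit="s"), cfg.drug_name.capitalize(), True, int(offsets[i]))
            )

    frame = pd.concat(frames, ignore_index=True)
    frame.insert(0, "tweet_id", [f"t{j:08d}" for j in range(len(frame))])
    planted_all = np.concatenate(planted)
    keep = planted_all != "retweet"
    gt = GroundTruth(
        user_ids=user_ids,
        anchor_days=anchor_days,
        planted_period=pd.Series(
            planted_all[keep], index=frame.loc[keep, "tweet_id"], name="planted_period"
        ),
        latents=lat,
    )
    events_df = pd.DataFrame(
        events,
        columns=["user_id", "when_utc", "names", "intake_confirmed", "utc_offset_seconds"],
    )
    return frame, events_df, gt


def _assemble_texts(
    rng, i, t_per, C, F, ind, pos_mix, pron_mix, pools, pron_pools, lex_pools, lat, nt
) -> list[str]:
    """Build token-soup texts for one user's tweets (vectorized draws)."""
    parts: list[list[str]] = [[] for _ in range(nt)]
    # content words by POS category
    for p in (0, 1):
        sel = np.flatnonzero(t_per == p)
        if sel.size == 0:
            continue
        c_sel = C[sel]
        total = int(c_sel.sum())
        if total:
            cum = np.cumsum(pos_mix[i, p])
            cats = np.searchsorted(cum, rng.random(total), side="right")
            cats = np.minimum(cats, len(_POS_CATS) - 1)
            owner = np.repeat(sel, c_sel)
            for ci, cname in enumerate(_POS_CATS):
                rows = owner[cats == ci]
                if rows.size == 0:
                    continue
                if cname == "pronoun":
                    scum = np.cumsum(pron_mix[i, p])
                    slots = np.searchsorted(scum, rng.random(rows.size), side="right")
                    slots = np.minimum(slots, len(_PRON_SLOTS) - 1)
                    for si, sname in enumerate(_PRON_SLOTS):
                        srows = rows[slots == si]
                        if srows.size:
                            words = pron_pools[sname][
                                rng.integers(0, len(pron_pools[sname]), srows.size)
                            ]
                            for r, w in zip(srows, words):
                                parts[r].append(w)
                else:
                    pool = pools[cname]
                    words = pool[rng.integers(0, len(pool), rows.size)]
                    for r, w in zip(rows, words):
                        parts[r].append(w)
    # function words (excluded POS categories)
    totF = int(F.sum())
    if totF:
        owner = np.repeat(np.arange(nt), F)
        words = pools["function"][rng.integers(0, len(pools["function"]), totF)]
        for r, w in zip(owner, words):
            parts[r].append(w)
    # planted lexicon words
    for key, mask in ind.items():
        rows = np.flatnonzero(mask)
        if rows.size:
            pool = lex_pools[key]
            words = pool[rng.integers(0, len(pool), rows.size)]
            for r, w in zip(rows, words):
                parts[r].append(w)
    # links and mentions
    has_link = rng.random(nt) < lat["p_link"][i, t_per]
    has_ment = rng.random(nt) < lat["p_mention"][i, t_per]
    for r in np.flatnonzero(has_link):
        parts[r].append("https://t.co/abc123")
    for r in np.flatnonzero(has_ment):
        parts[r].append("@amiga")
    texts = [" ".join(p) if p else "eh" for p in parts]
    return texts


def validate_against_windows(
    ground_truth: GroundTruth, labeled: pd.DataFrame
) -> pd.DataFrame:
    """Confusion table of planted vs recovered period labels.

    Under matched window configs the table must be diagonal (100%
    agreement); a deliberately mismatched washout shows up as off-diagonal
    mass.  Rows = planted, columns = recovered.
    """
    recovered = labeled.set_index("tweet_id")["period"]
    joined = pd.DataFrame({"planted": ground_truth.planted_period}).join(
        recovered, how="inner"
    )
    return pd.crosstab(joined["planted"], joined["period"])
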