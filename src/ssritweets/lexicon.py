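"""SSRI name lexicon and drug-mention detection.

The packaged lexicon is the study drug-name table: 135 generic and brand
names of the six SSRI generics (fluvoxamine, fluoxetine, paroxetine,
sertraline, citalopram, escitalopram), stored exactly as listed — including
the duplicated names (Citalopram appears both as a generic and as a brand;
Cipralex is listed under two generics) — together with the seven brand names
excluded for semantic ambiguity (Essential, Motivan, Estar, Traviata,
Pondera, Recital, Emergen), which are everyday Spanish words.  Applying the
exclusions leaves 128 active names; matching internally deduplicates so a
repeated name is never double-reported.

Matching is case-insensitive, Unicode-NFC-normalized, token-boundary
matching over the corpus tokenizer's token stream; multi-word names
("Paxil CR", "C Pram S") are matched as phrases, and the longest match wins
and consumes its tokens.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .text import tokenize

__all__ = [
    "GENERIC_NAMES",
    "DrugLexicon",
    "MentionEvent",
    "load_lexicon",
    "load_exclusions",
    "default_lexicon",
    "apply_exclusions",
    "detect_mentions",
    "scan_mentions",
    "mention_frequencies",
]

GENERIC_NAMES = (
    "Fluvoxamina",
    "Fluoxetina",
    "Paroxetina",
    "Sertralina",
    "Citalopram",
    "Escitalopram",
)


def _norm(token: str, accent_insensitive: bool) -> str:
    s = unicodedata.normalize("NFC", token).lower()
    if accent_insensitive:
        s = "".join(
            c
            for c in unicodedata.normalize("NFD", s)
            if not unicodedata.combining(c)
        )
    return s


def _phrase(name: str, accent_insensitive: bool) -> tuple[str, ...]:
    return tuple(_norm(t, accent_insensitive) for t in tokenize(name).tokens)


@dataclass
class DrugLexicon:
    """The SSRI name list with generic/brand grouping and exclusion set.

    ``entries`` keeps the raw rows as listed (duplicates included) so the
    name-count arithmetic 135 − 7 = 128 is reproducible; the matching index is
    built from the deduplicated active names.
    """

    entries: list[tuple[str, str, bool]]  # (name, generic_name, is_generic)
    excluded: set[str] = field(default_factory=set)
    accent_insensitive: bool = False
    match_hashtags: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self._index = None

    @property
    def n_raw(self) -> int:
        return len(self.entries)

    def active(self) -> list[tuple[str, str, bool]]:
        """Entries whose name is not excluded (duplicates as stored)."""
        excl = {_norm(n, False) for n in self.excluded}
        return [e for e in self.entries if _norm(e[0], False) not in excl]

    @property
    def n_active(self) -> int:
        return len(self.active())

    def active_names(self) -> list[str]:
        """Distinct active names, first-spelling-wins, original casing."""
        seen = {}
        for name, _, _ in self.active():
            seen.setdefault(_norm(name, False), name)
        return list(seen.values())

    def _matcher(self):
        if self._index is None:
            index: dict[str, list[tuple[tuple[str, ...], str]]] = {}
            for name in self.active_names():
                ph = _phrase(name, self.accent_insensitive)
                index.setdefault(ph[0], []).append((ph, name))
            for lst in index.values():
                lst.sort(key=lambda it: len(it[0]), reverse=True)
            self._index = index
        return self._index


@dataclass(frozen=True)
class MentionEvent:
    """One drug-mentioning tweet.

    ``intake_confirmed`` stands in for the study's manual curation step: it
    marks mentions judged to indicate that the author was actually taking the
    drug (as opposed to e.g. news or jokes about it).
    """

    user_id: str
    when_utc: pd.Timestamp
    matched_names: tuple[str, ...]
    intake_confirmed: bool


def _data(name: str):
    return resources.files("ssritweets.data").joinpath(name)


def load_lexicon(source=None, **options) -> DrugLexicon:
    """Load a drug-name lexicon TSV.

    Two layouts are accepted: the packaged long form with columns
    ``generic_name, name, is_generic`` (one entry per row, stored as
    listed), or a wide form with columns ``generic_name, brand_names``
    (comma-separated brands; the generic itself becomes an entry too).

    Raises on an empty table or on a generic name outside the six SSRIs.
    """
    if source is None:
        with resources.as_file(_data("ssri_names.tsv")) as p:
            return load_lexicon(p, **options)
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    if df.empty:
        raise ValueError("empty lexicon table")
    entries: list[tuple[str, str, bool]] = []
    if "brand_names" in df.columns:
        for row in df.itertuples(index=False):
            generic = row.generic_name.strip()
            _check_generic(generic)
            entries.append((generic, generic, True))
            for brand in str(row.brand_names).split(","):
                brand = brand.strip()
                if brand:
                    entries.append((brand, generic, False))
    else:
        for row in df.itertuples(index=False):
            generic = row.generic_name.strip()
            _check_generic(generic)
            entries.append((row.name.strip(), generic, row.is_generic in ("1", "True", "true")))
    return DrugLexicon(entries=entries, **options)


def _check_generic(generic: str) -> None:
    if generic not in GENERIC_NAMES:
        raise ValueError(f"unknown SSRI generic: {generic!r}")


def load_exclusions(source=None) -> set[str]:
    """The ambiguity exclusion list (default: the packaged 7 names)."""
    if source is None:
        with resources.as_file(_data("ambiguous_exclusions.txt")) as p:
            return load_exclusions(p)
    with open(source, "r", encoding="utf-8") as fh:
        return {ln.strip() for ln in fh if ln.strip()}


def default_lexicon(apply_ambiguity_exclusions: bool = True, **options) -> DrugLexicon:
    """The packaged lexicon, with the ambiguity exclusions applied by default."""
    lex = load_lexicon(**options)
    if apply_ambiguity_exclusions:
        lex = apply_exclusions(lex, load_exclusions())
    return lex


def apply_exclusions(lexicon: DrugLexicon, names: Iterable[str]) -> DrugLexicon:
    """Extend the exclusion set; raw entries stay untouched.

    A name absent from the lexicon produces a collected warning, not an
    error.
    """
    names = set(names)
    if not names:
        raise ValueError("no exclusion names given")
    known = {_norm(e[0], False) for e in lexicon.entries}
    warnings = list(lexicon.warnings)
    accepted = set(lexicon.excluded)
    for name in sorted(names):
        if _norm(name, False) not in known:
            warnings.append(f"exclusion name not in lexicon: {name}")
        else:
            accepted.add(name)
    return DrugLexicon(
        entries=lexicon.entries,
        excluded=accepted,
        accent_insensitive=lexicon.accent_insensitive,
        match_hashtags=lexicon.match_hashtags,
        warnings=warnings,
    )


def detect_mentions(text: str, lexicon: DrugLexicon) -> list[str]:
    """Active lexicon names mentioned in a tweet, each reported once.

    Longest-match-wins over the token stream: "Paxil CR" consumes both
    tokens, so it does not additionally report "Paxil".  Hashtag tokens do
    not match unless the lexicon was built with ``match_hashtags=True``.
    """
    index = lexicon._matcher()
    tt = tokenize(text)
    toks = []
    for tok, kind in zip(tt.tokens, tt.kinds):
        if kind == "hashtag" and lexicon.match_hashtags:
            toks.append(_norm(tok[1:], lexicon.accent_insensitive))
        else:
            toks.append(_norm(tok, lexicon.accent_insensitive))
    found: dict[str, None] = {}
    i, n = 0, len(toks)
    while i < n:
        cands = index.get(toks[i])
        if cands:
            for phrase, name in cands:
                k = len(phrase)
                if i + k <= n and tuple(toks[i : i + k]) == phrase:
                    found.setdefault(name)
                    i += k
                    break
            else:
                i += 1
        else:
            i += 1
    return list(found)


def scan_mentions(
    frame: pd.DataFrame,
    lexicon: DrugLexicon,
    intake_confirmed: bool = True,
) -> pd.DataFrame:
    """Scan a tweets frame for drug mentions.

    Returns a mention-events frame (user_id, when_utc, names, intake_confirmed)
    with ``names`` comma-joined.  ``intake_confirmed`` marks every detection
    with the given flag; real curation data can overwrite the column.
    Cheap prefilter: a tweet is only tokenized when a lexicon word occurs as
    a substring.
    """
    names = lexicon.active_names()
    probes = sorted({_norm(tokenize(n).tokens[0], lexicon.accent_insensitive) for n in names})
    rows = []
    for row in frame.itertuples(index=False):
        low = _norm(row.text, lexicon.accent_insensitive)
        if not any(p in low for p in probes):
            continue
        hits = detect_mentions(row.text, lexicon)
        if hits:
            rows.append((row.user_id, row.created_at_utc, ",".join(hits), intake_confirmed))
    return pd.DataFrame(
        rows, columns=["user_id", "when_utc", "names", "intake_confirmed"]
    )


def mention_frequencies(frames_or_texts, lexicon: DrugLexicon) -> pd.DataFrame:
    """Tweet counts per active name, sorted descending.

    A tweet mentioning k distinct names increments k rows; totals therefore
    equal the number of (tweet, name) detection pairs.
    """
    if isinstance(frames_or_texts, pd.DataFrame):
        texts: Sequence[str] = frames_or_texts["text"].tolist()
    else:
        texts = list(frames_or_texts)
    counts: dict[str, int] = {}
    for text in texts:
        for name in detect_mentions(text, lexicon):
            counts[name] = counts.get(name, 0) + 1
    out = pd.DataFrame(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
                       columns=["name", "count"])
    return out
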