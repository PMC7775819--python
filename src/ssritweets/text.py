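"""Tokenization, part-of-speech tagging and word lexicons.

The tokenizer is a Twitter-aware regex tokenizer: @mentions, #hashtags and
URLs are kept as single tokens with their own kind, words keep Spanish
accented characters, and everything else falls through to number/punct/other
kinds.  Tagging is a pluggable contract — any object with a
``tag(tokens, kinds)`` method returning :class:`TaggedToken` sequences — with
a deterministic dictionary tagger shipped as the default engine so the whole
pipeline runs and tests without an external NLP tool.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

__all__ = [
    "TokenizedTweet",
    "TaggedToken",
    "tokenize",
    "DictionaryTagger",
    "WordLexicons",
    "load_word_lexicon",
    "load_wordlist",
    "default_tagger",
    "default_lexicons",
    "EMOTIONS",
    "POS_TAGS",
    "EXCLUDED_POS",
]

EMOTIONS = ("happiness", "sadness", "fear", "anger", "disgust", "surprise")

POS_TAGS = (
    "verb",
    "noun",
    "pronoun",
    "adverb",
    "adjective",
    "conjunction",
    "interjection",
    "punctuation",
    "determiner",
    "adposition",
    "number",
    "date",
    "other",
)

#: Grammatical categories excluded from the POS-percentage denominator.
EXCLUDED_POS = frozenset(
    {
        "conjunction",
        "interjection",
        "punctuation",
        "determiner",
        "adposition",
        "number",
        "date",
    }
)

# Order matters: URLs before words so "https" is not split; mentions and
# hashtags as single tokens; words include Spanish accents and ñ/ü.
_TOKEN_RE = re.compile(
    r"""
    https?://\S+ | www\.\S+            # urls
    | @\w+                             # user mentions
    | \#\w+                            # hashtags
    | \d+(?:[.,:]\d+)*                 # numbers / times
    | [a-záéíóúüñA-ZÁÉÍÓÚÜÑ]+          # words
    | \S                               # any other single non-space char
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class TokenizedTweet:
    tokens: tuple[str, ...]
    kinds: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


def _kind_of(tok: str) -> str:
    c0 = tok[0]
    if c0 == "@" and len(tok) > 1:
        return "user_mention"
    if c0 == "#" and len(tok) > 1:
        return "hashtag"
    if tok.startswith("http://") or tok.startswith("https://") or tok.startswith("www."):
        return "url"
    if c0.isdigit():
        return "number"
    if c0.isalpha():
        return "word"
    if unicodedata.category(c0).startswith("P") or c0 in "¡¿$+<>=|~^`":
        return "punct"
    return "other"


def tokenize(text: str) -> TokenizedTweet:
    """Split tweet text into tokens with parallel token kinds.

    The tokenizer drops nothing: retweet prefixes, punctuation and emoji all
    surface as tokens (filtering is a separate concern).  Word tokens keep
    their original casing; downstream lexicon lookups lowercase as needed.
    """
    toks = _TOKEN_RE.findall(text)
    return TokenizedTweet(tokens=tuple(toks), kinds=tuple(_kind_of(t) for t in toks))


@dataclass(frozen=True)
class TaggedToken:
    token: str
    pos: str
    pronoun_person: int | None = None  # 1, 2 or 3; personal pronouns only
    pronoun_number: str | None = None  # "singular" | "plural"


_NONWORD_POS = {
    "url": "other",
    "user_mention": "other",
    "hashtag": "other",
    "punct": "punctuation",
    "number": "number",
    "other": "other",
}


class DictionaryTagger:
    """Deterministic dictionary POS tagger.

    A total function on word tokens: words found in the dictionary receive
    their listed category (personal pronouns also person/number); unknown
    words are tagged ``other`` and counted in :attr:`misses` so tagging
    coverage is reportable.  Non-word token kinds map to fixed categories
    (url/user_mention/hashtag → other, punct → punctuation, number → number).
    """

    def __init__(self, entries: Mapping[str, tuple[str, int | None, str | None]]):
        self.entries = dict(entries)
        self.misses = 0
        self.hits = 0

    @classmethod
    def from_tsv(cls, source) -> "DictionaryTagger":
        entries: dict[str, tuple[str, int | None, str | None]] = {}
        lines = _read_lines(source)
        header = lines[0].split("\t")
        assert header[0] == "word"
        for line in lines[1:]:
            parts = line.split("\t")
            word = parts[0].lower()
            pos = parts[1]
            person = int(parts[2]) if len(parts) > 2 and parts[2] else None
            number = parts[3] if len(parts) > 3 and parts[3] else None
            entries[word] = (pos, person, number)
        return cls(entries)

    def tag(self, tokens: Sequence[str], kinds: Sequence[str]) -> list[TaggedToken]:
        out = []
        get = self.entries.get
        for tok, kind in zip(tokens, kinds):
            if kind == "word":
                hit = get(tok.lower())
                if hit is None:
                    self.misses += 1
                    out.append(TaggedToken(tok, "other"))
                else:
                    self.hits += 1
                    out.append(TaggedToken(tok, hit[0], hit[1], hit[2]))
            else:
                out.append(TaggedToken(tok, _NONWORD_POS[kind]))
        return out

    def coverage(self) -> float:
        """Fraction of word tokens found in the dictionary so far."""
        seen = self.hits + self.misses
        return self.hits / seen if seen else float("nan")


@dataclass(frozen=True)
class WordLexicons:
    """The word lexicons driving indicator features.

    ``emotions`` maps word → one of the six emotion categories, ``sentiment``
    maps word → positive/negative, ``negations`` is a word set.  All matching
    downstream is exact, case-insensitive, on word tokens.
    """

    emotions: Mapping[str, str]
    sentiment: Mapping[str, str]
    negations: frozenset[str]

    def __post_init__(self):
        if not self.emotions or not self.sentiment or not self.negations:
            raise ValueError("empty lexicon")
        bad = set(self.emotions.values()) - set(EMOTIONS)
        if bad:
            raise ValueError(f"unknown emotion categories: {sorted(bad)}")
        bad = set(self.sentiment.values()) - {"positive", "negative"}
        if bad:
            raise ValueError(f"unknown polarities: {sorted(bad)}")


def _read_lines(source) -> list[str]:
    if hasattr(source, "read"):
        data = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = fh.read()
    return [ln for ln in data.splitlines() if ln.strip()]


def load_word_lexicon(source, value_column: str) -> dict[str, str]:
    """Read a two-column word lexicon TSV (word, category)."""
    lines = _read_lines(source)
    header = lines[0].split("\t")
    if header[0] != "word" or value_column not in header:
        raise ValueError(f"expected columns word, {value_column}; got {header}")
    vi = header.index(value_column)
    out = {}
    for line in lines[1:]:
        parts = line.split("\t")
        out[parts[0].lower()] = parts[vi]
    if not out:
        raise ValueError("empty lexicon")
    return out


def load_wordlist(source) -> frozenset[str]:
    """Read a one-expression-per-line word list (e.g. negations)."""
    return frozenset(w.strip().lower() for w in _read_lines(source))


def _data(name: str):
    return resources.files("ssritweets.data").joinpath(name)


def default_tagger() -> DictionaryTagger:
    """Fresh dictionary tagger from the packaged Spanish word list."""
    with resources.as_file(_data("pos_dictionary.tsv")) as p:
        return DictionaryTagger.from_tsv(p)


def default_lexicons() -> WordLexicons:
    """Packaged synthetic stand-in word lexicons.

    The emotion and sentiment tables are small synthetic Spanish word lists
    built for this package (the reference lexicons they emulate are not
    redistributable); the negation list is the package's own default.
    """
    with resources.as_file(_data("synthetic_emotion_lexicon.tsv")) as p:
        emotions = load_word_lexicon(p, "emotion")
    with resources.as_file(_data("synthetic_sentiment_lexicon.tsv")) as p:
        sentiment = load_word_lexicon(p, "polarity")
    with resources.as_file(_data("negation_words.txt")) as p:
        negations = load_wordlist(p)
    return WordLexicons(emotions=emotions, sentiment=sentiment, negations=negations)
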