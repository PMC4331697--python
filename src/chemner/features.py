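"""Feature extraction for the sequence labeler.

Every feature is a plain ``group=value`` string; the CRF engine indexes them.
Feature groups mirror the ingredients that matter for chemical names:

* linguistic — surface token, lemma, POS, chunk, dependency label/head;
* orthographic — capitalization class, digit/capital counting bins, symbol
  flags, Greek-letter flags (names and glyphs);
* morphological — prefixes, suffixes and character n-grams of 2–4
  characters, word shape (``Abc:1234`` -> ``Aaa#1111``);
* domain knowledge — case-insensitive longest-match lexicon hits;
* local context — either windows (neighbour attributes copied in) or
  conjunctions (attributes concatenated across a window), over the offset
  windows {-1,0}, {-2,-1}, {0,1}, {-1,1}, {-3,-1}.

The default configuration is the empirically best one: every group enabled
except dependency parsing and capitalization, with conjunctions for context.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .types import Token

logger = logging.getLogger(__name__)

ALL_GROUPS = frozenset({
    "token", "lemma", "pos", "chunk", "dependency",
    "capitalization", "counting", "symbols", "greek",
    "char_ngrams", "suffix", "prefix", "word_shape",
    "dictionary", "context_windows", "context_conjunctions",
})

#: best-performing configuration: drop dependency parsing and capitalization,
#: use conjunctions rather than windows for local context
BEST_GROUPS = ALL_GROUPS - {"dependency", "capitalization", "context_windows"}

DEFAULT_WINDOWS = ((-1, 0), (-2, -1), (0, 1), (-1, 1), (-3, -1))


@dataclass(frozen=True)
class FeatureConfig:
    enabled_groups: frozenset = BEST_GROUPS
    ngram_lengths: tuple = (2, 3, 4)
    affix_lengths: tuple = (2, 3, 4)
    context_windows: tuple = DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        unknown = set(self.enabled_groups) - ALL_GROUPS
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")
        if {"context_windows", "context_conjunctions"} <= set(
            self.enabled_groups
        ):
            raise ValueError(
                "context_windows and context_conjunctions are mutually "
                "exclusive"
            )
        for a, b in self.context_windows:
            if a > b:
                raise ValueError(f"bad window ({a},{b}): first > second")

    def without(self, *groups: str) -> "FeatureConfig":
        return FeatureConfig(
            enabled_groups=self.enabled_groups - set(groups),
            ngram_lengths=self.ngram_lengths,
            affix_lengths=self.affix_lengths,
            context_windows=self.context_windows,
        )

    def enabled(self, group: str) -> bool:
        return group in self.enabled_groups


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------


def _norm(s: str) -> str:
    return unicodedata.normalize("NFKC", s).lower()


class Lexicon:
    """A dictionary of known chemical terms for gazetteer features.

    Terms are matched case-insensitively (after NFKC normalization) against
    whitespace-split words, requiring token-boundary alignment; multi-word
    terms are space-separated in the source file.
    """

    def __init__(self, terms: Iterable[str] = ()) -> None:
        self._terms: dict[str, list[tuple[str, ...]]] = {}
        self._n = 0
        for term in terms:
            self.add(term)

    def add(self, term: str) -> None:
        words = tuple(_norm(w) for w in term.split())
        if not words:
            return
        self._terms.setdefault(words[0], []).append(words)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    @classmethod
    def from_file(cls, path) -> "Lexicon":
        lex = cls()
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.strip()
                if line and not line.startswith("#"):
                    lex.add(line)
        return lex

    def to_file(self, path) -> None:
        seen = set()
        with open(path, "w", encoding="utf-8") as fh:
            for variants in self._terms.values():
                for words in variants:
                    term = " ".join(words)
                    if term not in seen:
                        seen.add(term)
                        fh.write(term + "\n")

    def longest_match(self, words: Sequence[str], i: int) -> int:
        """Longest m such that words[i:i+m] is a term; 0 if none."""
        first = words[i]
        best = 0
        for cand in self._terms.get(first, ()):
            m = len(cand)
            if m > best and tuple(words[i : i + m]) == cand:
                best = m
        return best


def dictionary_features(
    tokens: Sequence[Token], lexicon: Optional[Lexicon]
) -> list[list[str]]:
    """Leftmost-longest lexicon matching, aligned with token boundaries.

    Matched tokens receive positional ``LEXICON=B`` / ``LEXICON=I`` features.
    """
    feats: list[list[str]] = [[] for _ in tokens]
    if lexicon is None or len(lexicon) == 0:
        return feats
    words = [_norm(t.surface) for t in tokens]
    i = 0
    while i < len(words):
        m = lexicon.longest_match(words, i)
        if m:
            feats[i].append("LEXICON=B")
            for j in range(i + 1, i + m):
                feats[j].append("LEXICON=I")
            i += m
        else:
            i += 1
    return feats


# ---------------------------------------------------------------------------
# per-token feature groups
# ---------------------------------------------------------------------------


def word_shape(surface: str) -> str:
    """Map uppercase->A, lowercase->a, digit->1, anything else->#."""
    if not surface:
        raise ValueError("word_shape of empty string")
    out = []
    for ch in surface:
        if ch.isupper():
            out.append("A")
        elif ch.islower():
            out.append("a")
        elif ch.isdigit():
            out.append("1")
        else:
            out.append("#")
    return "".join(out)


_GREEK_NAMES = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lambda", "mu", "nu", "xi", "omicron", "pi", "rho",
    "sigma", "tau", "upsilon", "phi", "chi", "psi", "omega",
)
_GREEK_GLYPHS = "αβγδεζηθικλμνξοπρστυφχψω" + "ΑΒΓΔΕΖΗΘΙΚΛΜΝΞΟΠΡΣΤΥΦΧΨΩ"

_SYMBOL_CLASSES = (
    ("Dash", "-"), ("Dot", "."), ("Comma", ","), ("Slash", "/"),
    ("Parenthesis", "()"), ("Bracket", "[]{}"), ("Plus", "+"),
    ("Percent", "%"), ("Apostrophe", "'"), ("Colon", ":"),
    ("Semicolon", ";"), ("Equals", "="),
)

_COUNT_BINS = ("No", "One", "Two", "ThreeOrMore")


def _count_bin(n: int, what: str) -> str:
    return _COUNT_BINS[min(n, 3)] + what


def capitalization_feature(surface: str) -> str:
    letters = [c for c in surface if c.isalpha()]
    if not letters:
        return "CAP=NoLetter"
    if len(letters) == 1 and letters[0].isupper() and len(surface) == 1:
        return "CAP=SingleCap"
    if all(c.isupper() for c in letters):
        return "CAP=AllCaps"
    if all(c.islower() for c in letters):
        return "CAP=LowerCase"
    if surface[0].isupper() and all(c.islower() for c in letters[1:]):
        return "CAP=StartCap"
    return "CAP=MixedCase"


def orthographic_features(token: Token, config: FeatureConfig) -> list[str]:
    s = token.surface
    feats: list[str] = []
    if config.enabled("capitalization"):
        feats.append(capitalization_feature(s))
    if config.enabled("counting"):
        feats.append("COUNT=" + _count_bin(sum(c.isdigit() for c in s), "Digit"))
        feats.append("COUNT=" + _count_bin(sum(c.isupper() for c in s), "Cap"))
    if config.enabled("symbols"):
        for name, chars in _SYMBOL_CLASSES:
            if any(c in s for c in chars):
                feats.append(f"SYM={name}")
    if config.enabled("greek"):
        low = s.lower()
        for name in _GREEK_NAMES:
            if name in low:
                feats.append(f"GREEK={name}")
        if any(c in _GREEK_GLYPHS for c in s):
            feats.append("GREEK=glyph")
    return feats


def morphological_features(token: Token, config: FeatureConfig) -> list[str]:
    s = token.surface
    feats: list[str] = []
    if config.enabled("prefix"):
        for n in config.affix_lengths:
            if len(s) >= n:
                feats.append(f"PRE{n}={s[:n]}")
    if config.enabled("suffix"):
        for n in config.affix_lengths:
            if len(s) >= n:
                feats.append(f"SUF{n}={s[-n:]}")
    if config.enabled("char_ngrams"):
        for n in config.ngram_lengths:
            for i in range(len(s) - n + 1):
                feats.append(f"NG{n}={s[i:i + n]}")
    if config.enabled("word_shape"):
        feats.append(f"SHAPE={word_shape(s)}")
    return feats


# ---------------------------------------------------------------------------
# context features
# ---------------------------------------------------------------------------

_WINDOW_ATTRS = ("lemma", "pos", "chunk")
_CONJ_ATTRS = ("lemma", "pos")


def _attr(tokens: Sequence[Token], i: int, attr: str) -> str:
    if i < 0:
        return "BOS"
    if i >= len(tokens):
        return "EOS"
    val = getattr(tokens[i], attr)
    return val if val is not None else "NA"


def context_features(
    index: int,
    tokens: Sequence[Token],
    mode: str,
    config: FeatureConfig,
) -> list[str]:
    """Local-context features for one token position.

    windows mode copies neighbour lemma/POS/chunk values tagged with their
    relative offset; conjunctions mode concatenates lemma (resp. POS) values
    across each window into a single feature.  Positions outside the sentence
    contribute ``BOS``/``EOS`` placeholders.
    """
    feats: list[str] = []
    for a, b in config.context_windows:
        positions = range(index + a, index + b + 1)
        if mode == "windows":
            for p in positions:
                off = p - index
                for attr in _WINDOW_ATTRS:
                    feats.append(
                        f"WIN[{a},{b}]{attr}@{off}={_attr(tokens, p, attr)}"
                    )
        elif mode == "conjunctions":
            for attr in _CONJ_ATTRS:
                joined = "|".join(_attr(tokens, p, attr) for p in positions)
                feats.append(f"CONJ[{a},{b}]{attr}={joined}")
        else:
            raise ValueError(f"unknown context mode {mode!r}")
    return feats


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

_LINGUISTIC_ATTR_GROUPS = {"lemma": "lemma", "pos": "pos", "chunk": "chunk"}


def build_features(
    tokens: Sequence[Token],
    lexicon: Optional[Lexicon] = None,
    config: FeatureConfig = FeatureConfig(),
) -> list[list[str]]:
    """Per-token feature lists for one sentence (the CRF's observations)."""
    n = len(tokens)
    feats: list[list[str]] = [[] for _ in range(n)]

    _avail: dict[str, bool] = {}

    def has_attr(group: str) -> bool:
        if group not in _avail:
            present = any(getattr(t, group) is not None for t in tokens)
            if not present and n:
                logger.warning(
                    "group %r enabled but no %s attributes present; skipped",
                    group, group,
                )
            _avail[group] = present
        return _avail[group]

    for i, tok in enumerate(tokens):
        f = feats[i]
        if config.enabled("token"):
            f.append(f"W={tok.surface}")
        if config.enabled("lemma") and has_attr("lemma"):
            f.append(f"LEMMA={(tok.lemma or tok.surface).lower()}")
        if config.enabled("pos") and has_attr("pos"):
            f.append(f"POS={tok.pos or 'NA'}")
        if config.enabled("chunk") and has_attr("chunk"):
            f.append(f"CHUNK={tok.chunk or 'NA'}")
        if config.enabled("dependency"):
            if tok.dep_label is not None:
                f.append(f"DEP={tok.dep_label}")
            if tok.dep_head is not None and 0 <= tok.dep_head < n:
                head = tokens[tok.dep_head]
                f.append(f"DEPHEAD={(head.lemma or head.surface).lower()}")
        f.extend(orthographic_features(tok, config))
        f.extend(morphological_features(tok, config))

    if config.enabled("dictionary"):
        for i, extra in enumerate(dictionary_features(tokens, lexicon)):
            feats[i].extend(extra)

    if config.enabled("context_windows"):
        for i in range(n):
            feats[i].extend(context_features(i, tokens, "windows", config))
    elif config.enabled("context_conjunctions"):
        for i in range(n):
            feats[i].extend(
                context_features(i, tokens, "conjunctions", config)
            )
    return feats


#: map feature-string prefixes to group names, used to strip groups post hoc
_PREFIX_TO_GROUP = [
    ("W=", "token"), ("LEMMA=", "lemma"), ("POS=", "pos"),
    ("CHUNK=", "chunk"), ("DEP=", "dependency"), ("DEPHEAD=", "dependency"),
    ("CAP=", "capitalization"), ("COUNT=", "counting"), ("SYM=", "symbols"),
    ("GREEK=", "greek"), ("NG", "char_ngrams"), ("SUF", "suffix"),
    ("PRE", "prefix"), ("SHAPE=", "word_shape"), ("LEXICON=", "dictionary"),
    ("WIN[", "context_windows"), ("CONJ[", "context_conjunctions"),
]


def feature_group(feature: str) -> str:
    for prefix, group in _PREFIX_TO_GROUP:
        if feature.startswith(prefix):
            return group
    raise ValueError(f"cannot classify feature {feature!r}")
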