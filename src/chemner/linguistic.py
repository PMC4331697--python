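"""Sentence splitting, chemistry-aware tokenization, linguistic tagging.

Tokenization follows the convention used by chemistry-tuned taggers: after a
base segmentation on whitespace and sentence punctuation, any token containing
``/``, ``-`` or ``.`` is further divided so that each such symbol becomes its
own single-character token.  This keeps fragments of systematic names (locants,
substituent stems) as separate observations for the sequence model.  Decimal
numbers (``0.5``) are exempt from the ``.`` split so that dose and quantity
tokens survive.

A deterministic rule-based fallback tagger (suffix-driven POS, identity
lowercasing lemmas, a simple noun-phrase chunker) ships with the package so
the whole pipeline runs with no external NLP tool; richer taggers can be
plugged in through the :class:`LinguisticTagger` protocol.
"""

from __future__ import annotations

import re
from importlib import resources as _importlib_resources
from typing import Iterable, Optional, Protocol, Sequence

from .types import Sentence, Token

# ---------------------------------------------------------------------------
# sentence splitting
# ---------------------------------------------------------------------------


def _load_resource_lines(name: str) -> list[str]:
    path = _importlib_resources.files("chemner.resources").joinpath(name)
    lines = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            lines.append(line)
    return lines


def load_abbreviation_exceptions() -> list[str]:
    """Strings whose trailing period never ends a sentence."""
    return _load_resource_lines("abbrev_exceptions.txt")


_DEFAULT_EXCEPTIONS = None

_BOUNDARY_RE = re.compile(r"[.!?]+(?=(\s+)[A-Z0-9])")


def split_sentences(
    doc_id: str,
    section: str,
    text: str,
    exceptions: Optional[Iterable[str]] = None,
) -> list[Sentence]:
    """Split a section into sentences, preserving offsets.

    A boundary is sentence-final punctuation followed by whitespace and an
    uppercase letter or digit, unless the punctuation closes a known
    abbreviation (``e.g.``, ``et al.``, ``Fig.`` ...) or a single-letter
    initial.  Concatenating the sentence slices plus the gaps between them
    reconstructs the section text exactly.
    """
    global _DEFAULT_EXCEPTIONS
    if exceptions is None:
        if _DEFAULT_EXCEPTIONS is None:
            _DEFAULT_EXCEPTIONS = load_abbreviation_exceptions()
        exceptions = _DEFAULT_EXCEPTIONS
    exceptions = tuple(exceptions)

    if not text.strip():
        return []

    cut_points: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()  # position just after the punctuation run
        prefix = text[:end]
        if any(prefix.endswith(exc) for exc in exceptions):
            continue
        # single-letter initial like "J. Smith"
        head = prefix[:-1]
        if re.search(r"(?:^|[\s(])[A-Za-z]$", head):
            continue
        cut_points.append(end)

    spans: list[tuple[int, int]] = []
    prev = 0
    for cut in cut_points:
        spans.append((prev, cut))
        prev = cut
    spans.append((prev, len(text)))

    sentences = []
    for s, e in spans:
        # trim surrounding whitespace but keep offsets exact
        piece = text[s:e]
        lstrip = len(piece) - len(piece.lstrip())
        rstrip = len(piece) - len(piece.rstrip())
        s2, e2 = s + lstrip, e - rstrip
        if s2 < e2:
            sentences.append(Sentence(doc_id, section, s2, e2, text[s2:e2]))
    return sentences


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

#: punctuation split off as separate tokens during base segmentation
_SPLIT_PUNCT = set(",;:!?()[]{}\"'")
#: symbols always divided into their own tokens afterwards
_DIVIDE = set("/-.")


def _base_chunks(text: str) -> list[tuple[int, str]]:
    """Whitespace chunks, then sentence punctuation split off."""
    out: list[tuple[int, str]] = []
    for m in re.finditer(r"\S+", text):
        start, chunk = m.start(), m.group()
        run_start = 0
        for i, ch in enumerate(chunk):
            if ch in _SPLIT_PUNCT:
                if run_start < i:
                    out.append((start + run_start, chunk[run_start:i]))
                out.append((start + i, ch))
                run_start = i + 1
        if run_start < len(chunk):
            out.append((start + run_start, chunk[run_start:]))
    return out


def _divide_symbols(start: int, piece: str) -> list[tuple[int, str]]:
    """Split at '/', '-' and '.', keeping digit.digit decimals intact."""
    out: list[tuple[int, str]] = []
    run_start = 0
    for i, ch in enumerate(piece):
        if ch in _DIVIDE:
            if (
                ch == "."
                and 0 < i < len(piece) - 1
                and piece[i - 1].isdigit()
                and piece[i + 1].isdigit()
            ):
                continue  # decimal point inside a number
            if run_start < i:
                out.append((start + run_start, piece[run_start:i]))
            out.append((start + i, ch))
            run_start = i + 1
    if run_start < len(piece):
        out.append((start + run_start, piece[run_start:]))
    return out


def tokenize(sentence: Sentence) -> list[Token]:
    """Tokenize a sentence in place; offsets stay in the section frame."""
    tokens: list[Token] = []
    base = sentence.start
    for off, piece in _base_chunks(sentence.text):
        for off2, sub in _divide_symbols(base + off, piece):
            tokens.append(Token(off2, off2 + len(sub), sub))
    sentence.tokens = tokens
    return tokens


# ---------------------------------------------------------------------------
# linguistic taggers
# ---------------------------------------------------------------------------


class LinguisticTagger(Protocol):
    """Contract for token-attribute providers.

    ``tag`` returns one ``(lemma, pos, chunk, dep_head, dep_label)`` tuple per
    input token (entries outside ``capabilities`` may be ``None``) and must
    never alter token boundaries.
    """

    name: str
    capabilities: frozenset  # subset of {lemma, pos, chunk, dependency}

    def tag(
        self, tokens: Sequence[Token]
    ) -> list[tuple]: ...


_PRONOUNS = {
    "i", "we", "you", "he", "she", "it", "they", "this", "these",
    "that", "those", "its", "their", "our",
}
_DETERMINERS = {"the", "a", "an", "each", "every", "no", "all", "both", "some"}
_PREPOSITIONS = {
    "of", "in", "on", "at", "by", "for", "with", "from", "to", "into",
    "during", "after", "before", "between", "under", "over", "against",
    "through", "without", "within", "via",
}
_CONJUNCTIONS = {"and", "or", "but", "nor", "while", "whereas"}
_AUX = {
    "is", "are", "was", "were", "be", "been", "being", "has", "have",
    "had", "do", "does", "did", "can", "could", "may", "might", "will",
    "would", "should", "must",
}
_ADVERB_SUFFIX = ("ly",)
_ADJ_SUFFIX = ("ous", "ive", "able", "ible", "ic", "ical", "al", "ful", "less")
_VERB_PAST_SUFFIX = ("ed",)
_VERB_GER_SUFFIX = ("ing",)


class FallbackTagger:
    """Deterministic rule-based tagger: suffix POS, identity lemma, NP chunks.

    Not a statistical tagger; accurate enough to give the CRF consistent
    lemma/POS/chunk signal on templated scientific prose.
    """

    name = "fallback"
    capabilities = frozenset({"lemma", "pos", "chunk"})

    def _pos(self, surface: str, is_first: bool) -> str:
        low = surface.lower()
        if re.fullmatch(r"[0-9]+(\.[0-9]+)?", surface):
            return "CD"
        if not any(c.isalnum() for c in surface):
            return surface if surface in ".,:;" else "SYM"
        if low in _PRONOUNS:
            return "PRP"
        if low in _DETERMINERS:
            return "DT"
        if low in _PREPOSITIONS:
            return "IN"
        if low in _CONJUNCTIONS:
            return "CC"
        if low in _AUX:
            return "VBD" if low in {"was", "were", "had", "did"} else "VBZ"
        if low.endswith(_ADVERB_SUFFIX) and len(low) > 3:
            return "RB"
        if low.endswith(_VERB_PAST_SUFFIX) and len(low) > 3:
            return "VBD"
        if low.endswith(_VERB_GER_SUFFIX) and len(low) > 4:
            return "VBG"
        if low.endswith(_ADJ_SUFFIX) and len(low) > 4:
            return "JJ"
        if surface[0].isupper() and not is_first:
            return "NNP"
        if low.endswith("s") and len(low) > 3:
            return "NNS"
        return "NN"

    def tag(self, tokens: Sequence[Token]) -> list[tuple]:
        out = []
        prev_chunk = "O"
        for i, tok in enumerate(tokens):
            pos = self._pos(tok.surface, is_first=(i == 0))
            lemma = tok.surface.lower()
            if pos.startswith("NN") or pos in {"JJ", "DT", "CD"}:
                chunk = "I-NP" if prev_chunk.endswith("NP") else "B-NP"
            elif pos.startswith("VB"):
                chunk = "I-VP" if prev_chunk.endswith("VP") else "B-VP"
            else:
                chunk = "O"
            prev_chunk = chunk
            out.append((lemma, pos, chunk, None, None))
        return out


class NullTagger:
    """A tagger with no capabilities; leaves tokens untouched."""

    name = "null"
    capabilities = frozenset()

    def tag(self, tokens: Sequence[Token]) -> list[tuple]:
        return [(None, None, None, None, None) for _ in tokens]


def annotate_linguistics(
    tokens: Sequence[Token], tagger: LinguisticTagger
) -> Sequence[Token]:
    """Enrich tokens in place with the tagger's capabilities."""
    tuples = tagger.tag(tokens)
    if len(tuples) != len(tokens):
        raise ValueError(
            f"tagger {tagger.name!r} returned {len(tuples)} attribute "
            f"tuples for {len(tokens)} tokens"
        )
    caps = tagger.capabilities
    for tok, (lemma, pos, chunk, head, deplabel) in zip(tokens, tuples):
        if "lemma" in caps:
            tok.lemma = lemma
        if "pos" in caps:
            tok.pos = pos
        if "chunk" in caps:
            tok.chunk = chunk
        if "dependency" in caps:
            tok.dep_head = head
            tok.dep_label = deplabel
    return tokens


def parse_tagger_exchange(text: str) -> list[tuple]:
    """Parse the tab-separated token-attribute exchange format.

    Lines are ``token  lemma  pos  chunk  head  deplabel``; ``-`` marks an
    absent attribute.  Used to ingest output of external-process taggers.
    """
    out = []
    for raw in text.splitlines():
        if not raw.strip():
            continue
        parts = raw.split("\t")
        parts += ["-"] * (6 - len(parts))
        _, lemma, pos, chunk, head, deplabel = parts[:6]
        out.append((
            None if lemma == "-" else lemma,
            None if pos == "-" else pos,
            None if chunk == "-" else chunk,
            None if head == "-" else int(head),
            None if deplabel == "-" else deplabel,
        ))
    return out
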