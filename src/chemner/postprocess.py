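"""Post-processing of model annotations.

Three stages, applied in order after harmonization:

1. parentheses correction — an annotation whose text contains an odd total
   number of round/square/curly brackets is a truncated chemical name and is
   removed;
2. abbreviation resolution — parenthesized short forms are paired with their
   long forms by the classic character-matching recognizer; when one form of
   a pair is annotated the other is added, and partially covered forms are
   expanded to their full span;
3. exclusion-list filtering — mention strings whose historical
   true-positive/false-positive log odds fall below a threshold are removed
   from the output (optional, threshold-tunable by 10-fold search).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .types import Annotation, Document, Sentence

_BRACKETS = set("()[]{}")


def parentheses_filter(
    annotations: Sequence[Annotation],
) -> list[Annotation]:
    """Drop annotations containing an odd number of bracket characters."""
    return [
        a
        for a in annotations
        if sum(c in _BRACKETS for c in a.text) % 2 == 0
    ]


# ---------------------------------------------------------------------------
# abbreviation resolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbbrevPair:
    """A (long form, parenthesized short form) definition in one sentence."""

    doc_id: str
    section: str
    long_start: int
    long_end: int
    long_text: str
    short_start: int
    short_end: int
    short_text: str


def _valid_short_form(sf: str) -> bool:
    if not (2 <= len(sf) <= 10):
        return False
    if len(sf.split()) > 2:
        return False
    if not any(c.isalpha() for c in sf):
        return False
    if not sf[0].isalnum():
        return False
    return True


def _find_best_long_form(sf: str, candidate: str) -> Optional[int]:
    """Right-to-left character matching; returns the start index of the long
    form within ``candidate``, or None.

    Each alphanumeric short-form character must appear, in order, in the
    candidate text; the first character must match at the start of a word.
    """
    s_index = len(sf) - 1
    l_index = len(candidate) - 1
    while s_index >= 0:
        c = sf[s_index].lower()
        if not c.isalnum():
            s_index -= 1
            continue
        while l_index >= 0 and (
            candidate[l_index].lower() != c
            or (
                s_index == 0
                and l_index > 0
                and candidate[l_index - 1].isalnum()
            )
        ):
            l_index -= 1
        if l_index < 0:
            return None
        s_index -= 1
        l_index -= 1
    return l_index + 1


def _single_word_fallback(sf: str, candidate: str) -> Optional[int]:
    """Chemistry adaptation for contracted abbreviations (e.g. EtOH).

    When strict in-order matching fails, accept the single word immediately
    before the parenthesis if it starts with the short form's first letter
    and contains every alphanumeric short-form character (case-insensitive).
    """
    stripped = candidate.rstrip()
    if not stripped:
        return None
    start = stripped.rfind(" ") + 1
    word = stripped[start:]
    letters = [c.lower() for c in sf if c.isalnum()]
    if not letters or not word:
        return None
    if word[0].lower() != letters[0]:
        return None
    if all(c in word.lower() for c in letters):
        return start
    return None


def detect_abbreviations(sentence: Sentence) -> list[AbbrevPair]:
    """Find (long form, short form) definition pairs in one sentence.

    Candidate short forms are parenthesized strings of 2-10 characters, at
    most two words, containing a letter, starting alphanumeric.  The long
    form is searched in the words preceding the parenthesis (at most
    ``min(|sf| + 5, |sf| * 2)`` words back).
    """
    text = sentence.text
    pairs: list[AbbrevPair] = []
    depth = 0
    open_pos = -1
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
            if depth == 1:
                open_pos = i
        elif ch == ")" and depth > 0:
            depth -= 1
            if depth == 0:
                sf = text[open_pos + 1 : i]
                pair = _match_pair(sentence, open_pos, i, sf)
                if pair is not None:
                    pairs.append(pair)
    return pairs


def _match_pair(
    sentence: Sentence, open_pos: int, close_pos: int, sf: str
) -> Optional[AbbrevPair]:
    if not _valid_short_form(sf):
        return None
    before = sentence.text[:open_pos].rstrip()
    if not before:
        return None
    max_words = min(len(sf) + 5, len(sf) * 2)
    words = before.split()
    candidate_words = words[-max_words:]
    cand_start = before.rfind(candidate_words[0], 0)
    # locate the candidate window precisely from the right
    idx = len(before)
    for w in reversed(candidate_words):
        idx = before.rfind(w, 0, idx)
    cand_start = idx
    candidate = before[cand_start:]
    rel = _find_best_long_form(sf, candidate)
    if rel is None:
        rel = _single_word_fallback(sf, candidate)
    if rel is None:
        return None
    long_text = candidate[rel:].rstrip()
    if not long_text or long_text.lower() == sf.lower():
        return None
    ls = sentence.start + cand_start + rel
    le = ls + len(long_text)
    return AbbrevPair(
        sentence.doc_id,
        sentence.section,
        ls,
        le,
        long_text,
        sentence.start + open_pos + 1,
        sentence.start + close_pos,
        sf,
    )


def abbreviation_resolution(
    annotations: Sequence[Annotation],
    pairs: Sequence[AbbrevPair],
    section_text: str,
) -> list[Annotation]:
    """Propagate annotations between paired long and short forms.

    For each pair: an annotation partially covering a form is expanded to the
    span union; if exactly one form overlaps an annotation, the other form is
    added as a new annotation (source ``"abbrev"``) inheriting its
    confidence.  Identical spans are merged keeping the higher confidence.
    """
    current = list(annotations)
    for pair in pairs:
        forms = (
            (pair.long_start, pair.long_end),
            (pair.short_start, pair.short_end),
        )
        hits: list[list[int]] = [[], []]
        for fi, (fs, fe) in enumerate(forms):
            for ai, a in enumerate(current):
                if (
                    a.doc_id == pair.doc_id
                    and a.section == pair.section
                    and a.start < fe
                    and fs < a.end
                ):
                    hits[fi].append(ai)
        # expand partial coverage to the full form span
        for fi, (fs, fe) in enumerate(forms):
            for ai in hits[fi]:
                a = current[ai]
                if a.start > fs or a.end < fe:
                    ns, ne = min(a.start, fs), max(a.end, fe)
                    current[ai] = a.with_span(ns, ne, section_text)
        # add the missing counterpart
        for have, miss in ((0, 1), (1, 0)):
            if hits[have] and not hits[miss]:
                fs, fe = forms[miss]
                conf = max(current[ai].confidence for ai in hits[have])
                current.append(
                    Annotation(
                        pair.doc_id,
                        pair.section,
                        fs,
                        fe,
                        section_text[fs:fe],
                        confidence=conf,
                        source="abbrev",
                    )
                )
    # merge identical spans, keeping max confidence
    best: dict[tuple, Annotation] = {}
    for a in current:
        key = (a.doc_id, a.section, a.start, a.end)
        if key not in best or a.confidence > best[key].confidence:
            best[key] = a
    return sorted(
        best.values(), key=lambda a: (a.doc_id, a.section, a.start, a.end)
    )


# ---------------------------------------------------------------------------
# exclusion list
# ---------------------------------------------------------------------------


@dataclass
class ExclusionList:
    """Case-insensitive mention strings filtered from the output."""

    entries: set = field(default_factory=set)
    theta_logodds: float = 0.3
    min_fp: int = 2

    def __contains__(self, mention: str) -> bool:
        return mention.lower() in self.entries

    def to_file(self, path, corpus_hash: str = "") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                f"# theta_logodds={self.theta_logodds} "
                f"min_fp={self.min_fp} corpus={corpus_hash}\n"
            )
            for entry in sorted(self.entries):
                fh.write(entry + "\n")

    @classmethod
    def from_file(cls, path) -> "ExclusionList":
        entries = set()
        theta, min_fp = 0.3, 2
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.strip()
                if line.startswith("#"):
                    for part in line[1:].split():
                        if part.startswith("theta_logodds="):
                            theta = float(part.split("=", 1)[1])
                        elif part.startswith("min_fp="):
                            min_fp = int(part.split("=", 1)[1])
                elif line:
                    entries.add(line.lower())
        return cls(entries, theta, min_fp)


def mention_log_odds(tp: int, fp: int) -> float:
    """Smoothed log odds ln((TP + 0.5) / (FP + 0.5)) of a mention string."""
    return math.log((tp + 0.5) / (fp + 0.5))


def build_exclusion_list(
    gold: Sequence[Annotation],
    predicted: Sequence[Annotation],
    theta: float = 0.3,
    min_fp: int = 2,
) -> ExclusionList:
    """Collect predicted mention strings that are historically wrong.

    For each distinct lowercased predicted mention, TP counts exact-span
    matches to gold and FP counts predictions with no exact-span match; the
    mention joins the list iff its smoothed log odds is below ``theta`` and
    it produced at least ``min_fp`` false positives.
    """
    gold_spans = {(g.doc_id, g.section, g.start, g.end) for g in gold}
    counts: dict[str, list[int]] = {}
    for p in predicted:
        key = p.text.lower()
        tp_fp = counts.setdefault(key, [0, 0])
        if (p.doc_id, p.section, p.start, p.end) in gold_spans:
            tp_fp[0] += 1
        else:
            tp_fp[1] += 1
    entries = {
        mention
        for mention, (tp, fp) in counts.items()
        if fp >= min_fp and mention_log_odds(tp, fp) < theta
    }
    return ExclusionList(entries, theta, min_fp)


def apply_exclusion_list(
    annotations: Sequence[Annotation], exclusion: ExclusionList
) -> list[Annotation]:
    """Remove annotations whose lowercased text is listed."""
    return [a for a in annotations if a.text not in exclusion]


def tune_exclusion_thresholds(
    documents: Sequence[Document],
    gold: Sequence[Annotation],
    predicted: Sequence[Annotation],
    theta_grid: Sequence[float] = (0.0, 0.3, 0.5, 1.0),
    min_fp_grid: Sequence[int] = (1, 2, 3),
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, int, float]:
    """10-fold grid search for exclusion-list thresholds.

    Documents are shuffled with ``seed`` and split into ``folds`` parts; for
    each grid point the list is built on the other folds and the F1 change
    from applying it is measured on the held-out fold.  Returns the grid
    point with the best mean F1 change (ties prefer the higher theta, then
    the higher min_fp) and that mean change, in percentage points.
    """
    from .evaluation import evaluate  # late import to avoid a cycle

    if len(documents) < folds:
        raise ValueError(
            f"{len(documents)} documents cannot be split into {folds} folds"
        )
    rng = np.random.default_rng(seed)
    doc_ids = [d.doc_id for d in documents]
    order = rng.permutation(len(doc_ids))
    fold_of = {
        doc_ids[j]: i % folds for i, j in enumerate(order)
    }

    results: dict[tuple[float, int], float] = {}
    for theta in theta_grid:
        for min_fp in min_fp_grid:
            deltas = []
            for k in range(folds):
                train_gold = [g for g in gold if fold_of[g.doc_id] != k]
                train_pred = [p for p in predicted if fold_of[p.doc_id] != k]
                test_gold = [g for g in gold if fold_of[g.doc_id] == k]
                test_pred = [p for p in predicted if fold_of[p.doc_id] == k]
                excl = build_exclusion_list(
                    train_gold, train_pred, theta, min_fp
                )
                before = evaluate(test_pred, test_gold, "exact").f1
                after = evaluate(
                    apply_exclusion_list(test_pred, excl),
                    test_gold,
                    "exact",
                ).f1
                deltas.append(after - before)
            results[(theta, min_fp)] = float(np.mean(deltas))

    best = max(
        results, key=lambda tm: (results[tm], tm[0], tm[1])
    )
    return best[0], best[1], results[best]
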