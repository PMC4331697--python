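"""Readers and writers for CHEMDNER-dialect corpus and prediction files.

Formats (all UTF-8, tab-separated, one record per line):

* abstracts:    ``doc_id  title  abstract``
* annotations:  ``doc_id  section(T|A)  start  end  text  [class]``
* CEM output:   ``doc_id  section:start:end  rank  confidence``
* CDI output:   ``doc_id  mention-string  rank  confidence``

Offsets are 0-based, end-exclusive, per section, in Unicode code points.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

from .types import (
    Annotation,
    CLASSES,
    Document,
    LabeledSequence,
    Sentence,
    Token,
    check_non_overlapping,
    validate_annotation_against,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class CorpusFormatError(ValueError):
    """Raised on malformed corpus or prediction files."""


# ---------------------------------------------------------------------------
# abstracts / annotations
# ---------------------------------------------------------------------------

def read_abstracts(path: PathLike) -> list[Document]:
    """Read an abstracts TSV into Documents, preserving input order."""
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            doc_id, title = parts[0], parts[1]
            abstract = "\t".join(parts[2:])
            if not doc_id:
                raise CorpusFormatError(f"{path}:{lineno}: empty doc_id")
            if doc_id in seen:
                raise CorpusFormatError(
                    f"{path}:{lineno}: duplicate doc_id {doc_id!r}"
                )
            seen.add(doc_id)
            docs.append(Document(doc_id, title, abstract))
    return docs


def write_abstracts(docs: Iterable[Document], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(f"{d.doc_id}\t{d.title}\t{d.abstract}\n")


def read_annotations(
    path: PathLike, corpus: Sequence[Document]
) -> list[Annotation]:
    """Read an annotations TSV, validating every span against its document.

    Unknown class strings are mapped to ``UNCLASSIFIED`` with a warning;
    offsets outside the section or a text/slice mismatch are errors.
    """
    by_id = {d.doc_id: d for d in corpus}
    anns: list[Annotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected >=5 fields, got {len(parts)}"
                )
            doc_id, section = parts[0], parts[1]
            if doc_id not in by_id:
                raise CorpusFormatError(
                    f"{path}:{lineno}: unknown doc_id {doc_id!r}"
                )
            try:
                start, end = int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise CorpusFormatError(
                    f"{path}:{lineno}: non-integer offsets"
                ) from exc
            text = parts[4]
            cls = parts[5] if len(parts) > 5 and parts[5] else None
            if cls is not None and cls not in CLASSES:
                logger.warning(
                    "%s:%d: unknown class %r mapped to UNCLASSIFIED",
                    path, lineno, cls,
                )
                cls = "UNCLASSIFIED"
            ann = Annotation(doc_id, section, start, end, text, cls=cls,
                             confidence=1.0, source="gold")
            try:
                validate_annotation_against(by_id[doc_id], ann)
            except ValueError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
            anns.append(ann)
    check_non_overlapping(anns)
    return anns


def write_annotations(anns: Iterable[Annotation], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in anns:
            cls = a.cls or ""
            fh.write(
                f"{a.doc_id}\t{a.section}\t{a.start}\t{a.end}\t{a.text}\t{cls}\n"
            )


# ---------------------------------------------------------------------------
# BIO encoding
# ---------------------------------------------------------------------------

def encode_bio(
    sentence: Sentence, gold: Sequence[Annotation]
) -> LabeledSequence:
    """Label a tokenized sentence with BIO tags from gold spans.

    Gold spans whose boundaries fall strictly inside a token are snapped
    outward to the covering tokens (logged); overlapping gold spans raise.
    """
    relevant = [
        a
        for a in gold
        if a.doc_id == sentence.doc_id
        and a.section == sentence.section
        and a.start < sentence.end
        and a.end > sentence.start
    ]
    check_non_overlapping(relevant)
    labels = ["O"] * len(sentence.tokens)
    for ann in sorted(relevant, key=lambda a: a.start):
        covered = [
            i
            for i, t in enumerate(sentence.tokens)
            if t.start < ann.end and t.end > ann.start
        ]
        if not covered:
            continue
        first, last = sentence.tokens[covered[0]], sentence.tokens[covered[-1]]
        if first.start < ann.start or last.end > ann.end:
            logger.warning(
                "%s/%s: span [%d,%d) snapped outward to token boundaries "
                "[%d,%d)",
                ann.doc_id, ann.section, ann.start, ann.end,
                first.start, last.end,
            )
        labels[covered[0]] = "B"
        for i in covered[1:]:
            labels[i] = "I"
    return LabeledSequence(sentence, labels)


def decode_bio(
    sentence: Sentence,
    labels: Sequence[str],
    section_text: str,
    confidence: float = 1.0,
    source: str = "model",
) -> list[Annotation]:
    """Turn a BIO labeling back into span annotations.

    An ``I`` following ``O`` is repaired by treating it as ``B`` (logged).
    """
    anns: list[Annotation] = []
    run: list[int] = []
    fixed = list(labels)
    prev = "O"
    for i, lab in enumerate(fixed):
        if lab == "I" and prev == "O":
            logger.warning(
                "%s/%s: I after O at token %d repaired to B",
                sentence.doc_id, sentence.section, i,
            )
            fixed[i] = lab = "B"
        prev = lab

    def flush() -> None:
        if run:
            first, last = sentence.tokens[run[0]], sentence.tokens[run[-1]]
            anns.append(
                Annotation(
                    sentence.doc_id,
                    sentence.section,
                    first.start,
                    last.end,
                    section_text[first.start : last.end],
                    confidence=confidence,
                    source=source,
                )
            )
            run.clear()

    for i, lab in enumerate(fixed):
        if lab == "B":
            flush()
            run.append(i)
        elif lab == "I":
            run.append(i)
        else:
            flush()
    flush()
    return anns


# ---------------------------------------------------------------------------
# CEM / CDI prediction files
# ---------------------------------------------------------------------------

def _check_ranks(rows: Sequence[tuple], rank_pos: int) -> None:
    per_doc: dict[str, list[int]] = {}
    for row in rows:
        per_doc.setdefault(row[0], []).append(row[rank_pos])
    for doc_id, ranks in per_doc.items():
        if ranks != list(range(1, len(ranks) + 1)):
            raise CorpusFormatError(
                f"non-contiguous ranks for document {doc_id!r}: {ranks}"
            )


def write_cem(
    predictions: Sequence[tuple[Annotation, int]], path: PathLike
) -> None:
    """Write ranked span predictions: ``doc_id  S:start:end  rank  conf``."""
    rows = [(a.doc_id, a, r) for a, r in predictions]
    _check_ranks(rows, 2)
    with open(path, "w", encoding="utf-8") as fh:
        for a, rank in predictions:
            fh.write(
                f"{a.doc_id}\t{a.section}:{a.start}:{a.end}\t{rank}\t"
                f"{a.confidence:.6f}\n"
            )


def write_cdi(
    predictions: Sequence[tuple[str, str, int, float]], path: PathLike
) -> None:
    """Write ranked mention strings: ``doc_id  string  rank  conf``."""
    _check_ranks(predictions, 2)
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id, mention, rank, conf in predictions:
            fh.write(f"{doc_id}\t{mention}\t{rank}\t{conf:.6f}\n")


def read_cem(
    path: PathLike, corpus: Sequence[Document]
) -> list[Annotation]:
    """Read a CEM prediction file back into validated annotations."""
    by_id = {d.doc_id: d for d in corpus}
    anns: list[Annotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 4 fields, got {len(parts)}"
                )
            doc_id, loc, _rank, conf = parts
            section, start, end = loc.split(":")
            if doc_id not in by_id:
                raise CorpusFormatError(
                    f"{path}:{lineno}: unknown doc_id {doc_id!r}"
                )
            doc = by_id[doc_id]
            text = doc.section_text(section)[int(start) : int(end)]
            ann = Annotation(
                doc_id, section, int(start), int(end), text,
                confidence=float(conf), source="file",
            )
            validate_annotation_against(doc, ann)
            anns.append(ann)
    return anns
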