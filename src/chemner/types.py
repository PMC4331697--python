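"""Core domain objects shared across the pipeline.

All character offsets are 0-based, end-exclusive, counted in Unicode code
points, and are relative to one document *section* (title ``T`` or abstract
``A``); the two sections are independent coordinate frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

SECTIONS = ("T", "A")

#: Entity classes used by CHEMDNER-style gold annotations.  The tagger itself
#: is trained on a single merged class; classes are carried through for
#: per-class recall reporting only.
CLASSES = (
    "SYSTEMATIC",
    "TRIVIAL",
    "ABBREVIATION",
    "FAMILY",
    "IDENTIFIER",
    "FORMULA",
    "MULTIPLE",
    "UNCLASSIFIED",
)

BIO_LABELS = ("O", "B", "I")


@dataclass(frozen=True)
class Document:
    """One abstract record: an identifier plus title and abstract text."""

    doc_id: str
    title: str
    abstract: str

    def section_text(self, section: str) -> str:
        if section == "T":
            return self.title
        if section == "A":
            return self.abstract
        raise ValueError(f"unknown section {section!r} (expected 'T' or 'A')")


@dataclass
class Annotation:
    """A character span in one section of one document.

    ``confidence`` is a probability in [0, 1]; gold annotations carry 1.0.
    ``source`` records provenance (a model id, ``"abbrev"`` or ``"gold"``).
    """

    doc_id: str
    section: str
    start: int
    end: int
    text: str
    cls: Optional[str] = None
    confidence: float = 1.0
    source: str = "gold"

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise ValueError(f"bad section {self.section!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad span [{self.start}, {self.end}) in {self.doc_id}"
            )
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.cls is not None and self.cls not in CLASSES:
            raise ValueError(f"unknown class {self.cls!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, other: "Annotation") -> bool:
        return (
            self.doc_id == other.doc_id
            and self.section == other.section
            and self.start < other.end
            and other.start < self.end
        )

    def with_span(self, start: int, end: int, section_text: str) -> "Annotation":
        return replace(self, start=start, end=end, text=section_text[start:end])


@dataclass
class Token:
    """A token with section-frame offsets and optional linguistic attributes."""

    start: int
    end: int
    surface: str
    lemma: Optional[str] = None
    pos: Optional[str] = None
    chunk: Optional[str] = None
    dep_head: Optional[int] = None
    dep_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError(f"bad token span [{self.start}, {self.end})")


@dataclass
class Sentence:
    """A sentence inside one section; ``text`` equals the section slice."""

    doc_id: str
    section: str
    start: int
    end: int
    text: str
    tokens: list[Token] = field(default_factory=list)


@dataclass
class LabeledSequence:
    """A tokenized sentence with one BIO label per token."""

    sentence: Sentence
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sentence.tokens):
            raise ValueError(
                f"{len(self.labels)} labels for "
                f"{len(self.sentence.tokens)} tokens"
            )
        prev = "O"
        for i, lab in enumerate(self.labels):
            if lab not in BIO_LABELS:
                raise ValueError(f"bad BIO label {lab!r} at position {i}")
            if lab == "I" and prev == "O":
                raise ValueError(f"I after O at position {i} (invalid BIO)")
            prev = lab


def validate_annotation_against(doc: Document, ann: Annotation) -> None:
    """Check the slice invariant: ``ann.text`` equals the section slice."""
    text = doc.section_text(ann.section)
    if ann.end > len(text):
        raise ValueError(
            f"{ann.doc_id}/{ann.section}: span [{ann.start}, {ann.end}) "
            f"outside section of length {len(text)}"
        )
    piece = text[ann.start : ann.end]
    if piece != ann.text:
        raise ValueError(
            f"{ann.doc_id}/{ann.section}[{ann.start}:{ann.end}]: "
            f"annotation text {ann.text!r} does not match slice {piece!r}"
        )


def check_non_overlapping(annotations: Sequence[Annotation]) -> None:
    """Raise if any two annotations in the same section intersect."""
    by_key: dict[tuple[str, str], list[Annotation]] = {}
    for a in annotations:
        by_key.setdefault((a.doc_id, a.section), []).append(a)
    for key, group in by_key.items():
        group = sorted(group, key=lambda a: (a.start, a.end))
        for prev, cur in zip(group, group[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping annotations in {key[0]}/{key[1]}: "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )
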