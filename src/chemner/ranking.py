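"""Confidence ranking of final annotations for CEM and CDI output.

CEM ranks every span per document by descending confidence (ties: title
before abstract, then ascending start, then ascending end).  CDI first
deduplicates by exact surface string per document, keeping the maximum
confidence per string, then ranks the survivors the same way.
"""

from __future__ import annotations

from typing import Sequence

from .types import Annotation

_SECTION_ORDER = {"T": 0, "A": 1}


def _sort_key(a: Annotation):
    return (
        -a.confidence,
        _SECTION_ORDER[a.section],
        a.start,
        a.end,
    )


def rank_cem(
    annotations: Sequence[Annotation],
) -> list[tuple[Annotation, int]]:
    """Per-document confidence-ranked spans as (annotation, rank) pairs."""
    by_doc: dict[str, list[Annotation]] = {}
    for a in annotations:
        by_doc.setdefault(a.doc_id, []).append(a)
    out: list[tuple[Annotation, int]] = []
    for doc_id in sorted(by_doc):
        ranked = sorted(by_doc[doc_id], key=_sort_key)
        out.extend((a, i + 1) for i, a in enumerate(ranked))
    return out


def rank_cdi(
    annotations: Sequence[Annotation],
) -> list[tuple[str, str, int, float]]:
    """Per-document ranked mention strings (exact-string deduplication).

    Returns (doc_id, mention string, rank, confidence) rows; each distinct
    surface string keeps its best-confidence occurrence.
    """
    best: dict[tuple[str, str], Annotation] = {}
    for a in annotations:
        key = (a.doc_id, a.text)
        if key not in best or _sort_key(a) < _sort_key(best[key]):
            best[key] = a
    by_doc: dict[str, list[Annotation]] = {}
    for (doc_id, _), a in best.items():
        by_doc.setdefault(doc_id, []).append(a)
    out: list[tuple[str, str, int, float]] = []
    for doc_id in sorted(by_doc):
        ranked = sorted(by_doc[doc_id], key=_sort_key)
        out.extend(
            (doc_id, a.text, i + 1, a.confidence)
            for i, a in enumerate(ranked)
        )
    return out
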