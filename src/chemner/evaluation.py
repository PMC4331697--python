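"""Scoring of span predictions against gold annotations.

Five span-matching strategies are supported: ``exact`` (both offsets equal),
``left`` (starts equal), ``right`` (ends equal), ``shared`` (either offset
equal) and ``overlap`` (any intersection).  Matching is one-to-one per
document section: exact pairs are resolved first, then remaining pairs
greedily by earliest start and longest overlap.  Precision, recall and F1
follow the standard definitions and are reported as percentages.

The module also carries the published CHEMDNER benchmark (P, R, F) triples
for the system family this package implements, used as an arithmetic
consistency check on the F1 formula, and the iterative feature-elimination
protocol used to select the default feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

from .types import Annotation

MODES = ("exact", "left", "right", "shared", "overlap")


def span_match(pred: Annotation, gold: Annotation, mode: str) -> bool:
    """Do two spans match under the given strategy?"""
    if pred.doc_id != gold.doc_id or pred.section != gold.section:
        return False
    if mode == "exact":
        return pred.start == gold.start and pred.end == gold.end
    if mode == "left":
        return pred.start == gold.start
    if mode == "right":
        return pred.end == gold.end
    if mode == "shared":
        return pred.start == gold.start or pred.end == gold.end
    if mode == "overlap":
        return pred.start < gold.end and gold.start < pred.end
    raise ValueError(f"unknown matching mode {mode!r}")


def round_pct(x: float) -> float:
    """Half-up rounding to two decimals, as printed in evaluation tables."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    mode: str = "exact"
    per_class_recall: dict = field(default_factory=dict)
    empty: bool = False  # no gold and no predictions

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def summary(self) -> str:
        return (
            f"{self.mode}: P={round_pct(self.precision):.2f} "
            f"R={round_pct(self.recall):.2f} F1={round_pct(self.f1):.2f} "
            f"(tp={self.tp} fp={self.fp} fn={self.fn})"
        )


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percentage scale)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _dedup(preds: Sequence[Annotation]) -> list[Annotation]:
    """Merge identical predicted spans, keeping the highest confidence."""
    best: dict[tuple, Annotation] = {}
    for p in preds:
        key = (p.doc_id, p.section, p.start, p.end)
        if key not in best or p.confidence > best[key].confidence:
            best[key] = p
    return list(best.values())


def _overlap_len(a: Annotation, b: Annotation) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def evaluate(
    preds: Sequence[Annotation],
    golds: Sequence[Annotation],
    mode: str = "exact",
) -> EvalResult:
    """One-to-one span matching; returns counts and P/R/F1 percentages."""
    if mode not in MODES:
        raise ValueError(f"unknown matching mode {mode!r}")
    preds = _dedup(preds)
    by_key: dict[tuple, tuple[list, list]] = {}
    for p in preds:
        by_key.setdefault((p.doc_id, p.section), ([], []))[0].append(p)
    for g in golds:
        by_key.setdefault((g.doc_id, g.section), ([], []))[1].append(g)

    tp = 0
    for ps, gs in by_key.values():
        matched_p: set[int] = set()
        matched_g: set[int] = set()
        # exact matches take priority in every mode
        gold_by_span = {(g.start, g.end): j for j, g in enumerate(gs)}
        for i, p in enumerate(ps):
            j = gold_by_span.get((p.start, p.end))
            if j is not None and j not in matched_g:
                matched_p.add(i)
                matched_g.add(j)
                tp += 1
        if mode != "exact":
            cands = [
                (p.start, -_overlap_len(p, g), g.start, i, j)
                for i, p in enumerate(ps)
                if i not in matched_p
                for j, g in enumerate(gs)
                if j not in matched_g and span_match(p, g, mode)
            ]
            for _, _, _, i, j in sorted(cands):
                if i not in matched_p and j not in matched_g:
                    matched_p.add(i)
                    matched_g.add(j)
                    tp += 1
    fp = len(preds) - tp
    fn = len(golds) - tp
    return EvalResult(
        tp, fp, fn, mode=mode, empty=(not preds and not golds)
    )


def evaluate_cdi(
    preds: dict[str, set], golds: dict[str, set]
) -> EvalResult:
    """Document-indexing evaluation: per-document mention-string sets."""
    tp = fp = fn = 0
    for doc_id in set(preds) | set(golds):
        p = preds.get(doc_id, set())
        g = golds.get(doc_id, set())
        tp += len(p & g)
        fp += len(p - g)
        fn += len(g - p)
    return EvalResult(
        tp, fp, fn, mode="cdi",
        empty=all(not v for v in preds.values())
        and all(not v for v in golds.values()),
    )


def class_recall(
    preds: Sequence[Annotation],
    golds: Sequence[Annotation],
    mode: str = "exact",
) -> dict[str, float]:
    """Recall percentage per gold class (predictions need not be classed)."""
    preds = _dedup(preds)
    by_key: dict[tuple, list[Annotation]] = {}
    for p in preds:
        by_key.setdefault((p.doc_id, p.section), []).append(p)
    hit: dict[str, list[int]] = {}
    for g in golds:
        if g.cls is None:
            continue
        counts = hit.setdefault(g.cls, [0, 0])
        counts[1] += 1
        if any(
            span_match(p, g, mode)
            for p in by_key.get((g.doc_id, g.section), ())
        ):
            counts[0] += 1
    return {
        cls: 100.0 * matched / total
        for cls, (matched, total) in hit.items()
    }


# ---------------------------------------------------------------------------
# published benchmark triples (percentage scale) for consistency checks
# ---------------------------------------------------------------------------

#: (table, row label, precision, recall, F1) as printed for the CHEMDNER
#: benchmark runs of the CRF system family implemented here.  Used only to
#: verify that the F1 formula reproduces every printed F value.
REPORTED_RESULTS = [
    # feature-elimination study (development set, exact matching)
    ("feature-elimination", "windows", 78.65, 78.75, 78.70),
    ("feature-elimination", "conjunctions", 81.37, 85.83, 83.54),
    ("feature-elimination", "token", 81.32, 85.86, 83.53),
    ("feature-elimination", "lemma", 78.51, 83.80, 81.07),
    ("feature-elimination", "pos", 81.75, 73.21, 77.25),
    ("feature-elimination", "chunk", 82.93, 80.83, 81.86),
    ("feature-elimination", "dependency", 85.88, 82.78, 84.30),
    ("feature-elimination", "capitalization", 85.97, 83.04, 84.48),
    ("feature-elimination", "counting", 85.86, 83.09, 84.45),
    ("feature-elimination", "symbols", 85.99, 82.96, 84.45),
    ("feature-elimination", "char_ngrams", 85.88, 82.53, 84.17),
    ("feature-elimination", "suffix", 85.74, 83.02, 84.36),
    ("feature-elimination", "prefix", 85.93, 83.03, 84.45),
    ("feature-elimination", "word_shape", 85.83, 82.42, 84.09),
    ("feature-elimination", "lexicons", 85.33, 81.48, 83.36),
    # final test-set results, entity mention task (exact matching)
    ("final-cem", "top-scoring", 89.09, 85.75, 87.39),
    ("final-cem", "official-run", 86.50, 85.66, 86.08),
    ("final-cem", "corrected-run", 87.35, 86.49, 86.92),
    ("final-cem", "order-1", 88.04, 84.89, 86.44),
    ("final-cem", "order-2", 88.35, 83.79, 86.01),
    ("final-cem", "post-processing", 88.67, 86.32, 87.48),
    # final test-set results, document indexing task
    ("final-cdi", "top-scoring", 87.02, 89.41, 88.20),
    ("final-cdi", "official-run", 86.35, 82.37, 84.31),
    ("final-cdi", "corrected-run", 87.07, 87.97, 87.52),
    ("final-cdi", "order-1", 88.00, 86.42, 87.20),
    ("final-cdi", "order-2", 88.14, 86.65, 87.39),
    ("final-cdi", "post-processing", 87.68, 87.81, 87.75),
    # relaxed shared matching, entity mention task
    ("final-cem-shared", "post-processing", 92.89, 90.34, 91.60),
]


def metric_consistency_deviations() -> list[float]:
    """|printed F1 - F1(P, R)| for every published benchmark triple."""
    return [
        abs(f - f1_from_pr(p, r))
        for _, _, p, r, f in REPORTED_RESULTS
    ]


# ---------------------------------------------------------------------------
# iterative feature elimination
# ---------------------------------------------------------------------------


@dataclass
class EliminationRound:
    baseline_f1: float
    candidates: dict  # group -> (P, R, F1) after removing that group
    removed: Optional[str]


def iterative_feature_elimination(
    train_data,
    dev_data,
    start_config=None,
    protected: frozenset = frozenset({"token"}),
    seed: int = 42,
    **trainer_kwargs,
) -> tuple[list[EliminationRound], "FeatureConfig"]:
    """Backward feature-group elimination driven by dev-set exact F1.

    Each round retrains one model per candidate single-group removal; the
    group whose removal most improves F1 is dropped.  Stops when no removal
    improves.  ``train_data`` / ``dev_data`` are (documents, gold, lexicon)
    triples; the protected groups (the surface-token feature by default) are
    never candidates.
    """
    from .features import FeatureConfig
    from . import pipeline

    config = start_config or FeatureConfig()
    t_docs, t_gold, lexicon = train_data
    d_docs, d_gold, _ = dev_data
    if not t_docs or not d_docs:
        raise ValueError("feature elimination needs non-empty corpora")

    def score(cfg) -> EvalResult:
        models = pipeline.train_models(
            t_docs, t_gold, lexicon, orders=(1,), config=cfg, seed=seed,
            **trainer_kwargs,
        )
        pred = pipeline.annotate_documents(
            d_docs, models, lexicon, parentheses=False, abbrev=False
        ).annotations
        return evaluate(pred, d_gold, "exact")

    rounds: list[EliminationRound] = []
    while True:
        base = score(config).f1
        candidates = sorted(
            g for g in config.enabled_groups if g not in protected
        )
        results = {}
        for g in candidates:
            res = score(config.without(g))
            results[g] = (res.precision, res.recall, res.f1)
        improving = {
            g: prf[2] for g, prf in results.items() if prf[2] > base
        }
        if improving:
            removed = max(improving, key=lambda g: (improving[g], g))
        else:
            removed = None
        rounds.append(EliminationRound(base, results, removed))
        if removed is None:
            return rounds, config
        config = config.without(removed)
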