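"""End-to-end orchestration: preprocessing, training, annotation.

The annotation chain mirrors the production pipeline: sentence splitting and
tokenization per section, linguistic tagging, feature extraction, decoding
with every model, cross-order harmonization, parentheses correction,
abbreviation resolution, optional exclusion-list filtering, and ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import corpus_io, postprocess
from .crf import AnnotationSet, CRFModel, harmonize, train_crf
from .features import FeatureConfig, Lexicon, build_features
from .linguistic import (
    FallbackTagger,
    LinguisticTagger,
    annotate_linguistics,
    split_sentences,
    tokenize,
)
from .types import Annotation, Document, SECTIONS, Sentence

logger = logging.getLogger(__name__)


def preprocess_document(
    doc: Document, tagger: Optional[LinguisticTagger] = None
) -> list[Sentence]:
    """Split, tokenize and tag both sections of one document."""
    tagger = tagger or FallbackTagger()
    sentences: list[Sentence] = []
    for section in SECTIONS:
        for sent in split_sentences(
            doc.doc_id, section, doc.section_text(section)
        ):
            tokenize(sent)
            if sent.tokens:
                annotate_linguistics(sent.tokens, tagger)
                sentences.append(sent)
    return sentences


def build_training_sequences(
    docs: Sequence[Document],
    gold: Sequence[Annotation],
    lexicon: Optional[Lexicon],
    config: FeatureConfig = FeatureConfig(),
    tagger: Optional[LinguisticTagger] = None,
):
    """(features, BIO labels) pairs for every sentence of the corpus."""
    tagger = tagger or FallbackTagger()
    sequences = []
    for doc in docs:
        doc_gold = [g for g in gold if g.doc_id == doc.doc_id]
        for sent in preprocess_document(doc, tagger):
            labeled = corpus_io.encode_bio(sent, doc_gold)
            feats = build_features(sent.tokens, lexicon, config)
            sequences.append((feats, labeled.labels))
    return sequences


def train_models(
    docs: Sequence[Document],
    gold: Sequence[Annotation],
    lexicon: Optional[Lexicon],
    orders: Sequence[int] = (1, 2),
    direction: str = "forward",
    config: FeatureConfig = FeatureConfig(),
    tagger: Optional[LinguisticTagger] = None,
    seed: int = 42,
    **crf_kwargs,
) -> list[CRFModel]:
    """Train one CRF per requested order on the same feature sequences."""
    sequences = build_training_sequences(docs, gold, lexicon, config, tagger)
    models = []
    for order in orders:
        model = train_crf(
            sequences,
            order=order,
            direction=direction,
            feature_config=config,
            seed=seed,
            **crf_kwargs,
        )
        logger.info(
            "trained order-%d %s model: %s", order, direction,
            model.training_meta,
        )
        models.append(model)
    return models


@dataclass
class AnnotationRun:
    """Final annotations plus per-stage counts for auditability."""

    annotations: list[Annotation]
    stage_counts: dict = field(default_factory=dict)


def annotate_documents(
    docs: Sequence[Document],
    models: Sequence[CRFModel],
    lexicon: Optional[Lexicon] = None,
    exclusion: Optional[postprocess.ExclusionList] = None,
    parentheses: bool = True,
    abbrev: bool = True,
    tagger: Optional[LinguisticTagger] = None,
) -> AnnotationRun:
    """Run the full annotation chain over a corpus.

    Documents are processed independently and results concatenated in input
    order, so the output is deterministic.
    """
    if not models:
        raise ValueError("at least one model is required")
    configs = {id(m.feature_config): m.feature_config for m in models}
    if len({tuple(sorted(c.enabled_groups)) for c in configs.values()}) > 1:
        raise ValueError("models disagree on feature configuration")
    config = models[0].feature_config
    tagger = tagger or FallbackTagger()

    counts = {"decoded": 0, "harmonized": 0, "parentheses": 0,
              "abbrev": 0, "exclusion": 0}
    final: list[Annotation] = []
    for doc in docs:
        sentences = preprocess_document(doc, tagger)
        feats_per_sent = [
            build_features(s.tokens, lexicon, config) for s in sentences
        ]
        sets = []
        for model in models:
            anns: list[Annotation] = []
            for sent, feats in zip(sentences, feats_per_sent):
                anns.extend(
                    model.decode(sent, feats, doc.section_text(sent.section))
                )
            sets.append(AnnotationSet(anns, model.model_id))
        counts["decoded"] += sum(len(s.annotations) for s in sets)

        merged = harmonize(sets).annotations
        counts["harmonized"] += len(merged)
        if parentheses:
            merged = postprocess.parentheses_filter(merged)
        counts["parentheses"] += len(merged)
        if abbrev:
            for section in SECTIONS:
                pairs = []
                for sent in sentences:
                    if sent.section == section:
                        pairs.extend(postprocess.detect_abbreviations(sent))
                if pairs:
                    section_anns = [
                        a for a in merged if a.section == section
                    ]
                    others = [a for a in merged if a.section != section]
                    merged = others + postprocess.abbreviation_resolution(
                        section_anns, pairs, doc.section_text(section)
                    )
        counts["abbrev"] += len(merged)
        if exclusion is not None:
            merged = postprocess.apply_exclusion_list(merged, exclusion)
        counts["exclusion"] += len(merged)
        merged.sort(key=lambda a: (a.section, a.start, a.end))
        final.extend(merged)
    return AnnotationRun(final, counts)


def cdi_sets(annotations: Sequence[Annotation]) -> dict[str, set]:
    """Per-document distinct mention-string sets (for CDI evaluation)."""
    out: dict[str, set] = {}
    for a in annotations:
        out.setdefault(a.doc_id, set()).add(a.text)
    return out
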