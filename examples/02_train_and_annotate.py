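"""Train order-1 and order-2 CRFs, harmonize, and rank the output.

The two models are decoded independently; harmonization keeps, within each
group of overlapping spans, the one with the highest posterior confidence.
Ranked CEM (spans) and CDI (distinct strings) lists are then produced.
"""

from chemner import (
    GeneratorConfig, annotate_documents, evaluate, generate_corpus,
    rank_cdi, rank_cem, train_models,
)

docs, gold, lexicon = generate_corpus(GeneratorConfig(n_docs=120, seed=3))
train_docs, test_docs = docs[:100], docs[100:]
test_ids = {d.doc_id for d in test_docs}
train_gold = [g for g in gold if g.doc_id not in test_ids]
test_gold = [g for g in gold if g.doc_id in test_ids]

models = train_models(train_docs, train_gold, lexicon, orders=(1, 2))
for m in models:
    print(f"{m.model_id}: {m.training_meta['n_features']} features, "
          f"{m.training_meta['iterations']} optimizer iterations")

run = annotate_documents(test_docs, models, lexicon)
print("pipeline stage counts:", run.stage_counts)
print(evaluate(run.annotations, test_gold, "exact").summary())

print("\ntop-ranked mentions of the first test document:")
doc_id = test_docs[0].doc_id
for ann, rank in rank_cem(run.annotations)[:5]:
    if ann.doc_id == doc_id:
        print(f"  rank {rank}: {ann.text!r} conf={ann.confidence:.3f}")
for doc, mention, rank, conf in rank_cdi(run.annotations)[:3]:
    print(f"  CDI {doc} rank {rank}: {mention!r} conf={conf:.3f}")
# Confidence is the posterior probability of the span's exact BIO labeling
# under the CRF, so rank 1 is the span the model is most certain about.
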