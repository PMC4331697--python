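"""Generate a synthetic CHEMDNER-style corpus and inspect it.

The generator plants chemical mentions of all seven annotation classes into
templated abstracts with exact gold offsets, and emits a matching lexicon.
"""

from collections import Counter

from chemner import GeneratorConfig, generate_corpus

docs, gold, lexicon = generate_corpus(GeneratorConfig(n_docs=50, seed=0))

print(f"{len(docs)} documents, {len(gold)} gold mentions, "
      f"{len(lexicon)} lexicon terms")
print("class distribution:", dict(Counter(g.cls for g in gold)))
print()
d = docs[0]
print("title:   ", d.title)
print("abstract:", d.abstract[:160], "...")
for g in gold[:5]:
    print(f"  {g.section}[{g.start}:{g.end}] {g.text!r:40s} {g.cls}")
# Each line shows one gold mention: its section (T=title, A=abstract),
# character offsets, surface string and annotation class.
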