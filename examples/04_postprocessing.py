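"""Post-processing: parentheses parity, abbreviations, exclusion list.

Shows the three output-correction stages on small inputs, including the
10-fold threshold search that selects the exclusion-list cut-offs.
"""

from chemner import (
    Annotation, GeneratorConfig, Sentence, apply_exclusion_list,
    build_exclusion_list, corrupt_predictions, detect_abbreviations,
    generate_corpus, parentheses_filter, tune_exclusion_thresholds,
)

# 1. parentheses parity: odd bracket counts mark truncated names
anns = [
    Annotation("D", "A", 0, 18, "1-(2-chlorophenyl)", confidence=.9, source="m"),
    Annotation("D", "A", 20, 29, "2-(chloro", confidence=.9, source="m"),
]
print("after parentheses filter:",
      [a.text for a in parentheses_filter(anns)])

# 2. abbreviation definition detection (long form <-> short form)
text = "Patients took non-steroidal anti-inflammatory drugs (NSAIDs) daily."
(pair,) = detect_abbreviations(Sentence("D", "A", 0, len(text), text))
print(f"abbreviation pair: {pair.long_text!r} <-> {pair.short_text!r}")

# 3. exclusion list: mentions that are historically wrong get filtered
docs, gold, _ = generate_corpus(GeneratorConfig(n_docs=30, seed=2))
preds = corrupt_predictions(gold, docs, seed=4, fp_rate=0.9, fn_rate=0.05)
theta, min_fp, delta = tune_exclusion_thresholds(
    docs, gold, preds, theta_grid=[0.0, 0.3, 0.5], min_fp_grid=[2, 3],
    seed=0,
)
excl = build_exclusion_list(gold, preds, theta, min_fp)
filtered = apply_exclusion_list(preds, excl)
print(f"tuned thresholds: log-odds < {theta}, min FP >= {min_fp} "
      f"(mean dF1 {delta:+.2f} points)")
print(f"exclusion list: {sorted(excl.entries)}")
print(f"predictions {len(preds)} -> {len(filtered)} after filtering")
# The planted homographs ("gold", "lead", ...) produce repeated false
# positives and end up on the list; true mentions survive.
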