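# Methods

## Model

`chemner` tags chemical mentions with linear-chain conditional random
fields over BIO labels. Sentences are the unit of labeling; the title and
abstract of a document are processed as independent sections with
independent character-offset frames (0-based, end-exclusive, Unicode code
points).

Two model orders are provided. The order-1 chain conditions each label on
its predecessor. The order-2 chain is realized by **label-pair state
expansion**: states are consecutive label pairs (`^|O`, `O|B`, `B|I`, ...)
and a first-order chain is trained over the expanded alphabet, with
emission weights tied to the full pair state. This is the standard
construction and defines the same model family as a native second-order
chain while reusing all order-1 machinery; a small-instance test verifies
that an order-2 model with weights tied to an order-1 model decodes
identically. Orders above 2 are deliberately not supported — their training
cost grows steeply and, applied separately, they do not improve on order 1.

A hard label grammar (no `I` without a preceding `B`/`I`, expressed in the
model's internal parsing direction) is imposed as transition masks, so
Viterbi decoding can only emit valid BIO sequences. `backward` parsing
reverses every sequence before training and re-reverses at decode; it is
kept as an option flag because it does not help for chemicals, unlike for
gene/protein mentions.

Training minimizes the negative log-likelihood with a Gaussian prior
(variance 1.0, i.e. penalty 0.5·‖w‖²) by L-BFGS, starting from zero
weights. Optimization is deterministic given the data, so retraining
reproduces bit-identical models. Defaults: iteration cap 500 (small
corpora converge in well under 100), projected-gradient tolerance 1e-3.
The forward–backward recursions run in log space, batched across sentences
padded to the longest length; `-1e30` serves as effective −∞ so masked
states survive arithmetic without NaNs.

### Span confidence

The confidence of a decoded span is the **posterior probability of its
exact label subsequence** (`B I … I` over the span's tokens), computed by
constrained forward–backward: the lattice is re-run with all states whose
emitted label disagrees with the span pinned out, and the constrained
partition function is divided by the full one. This is a true probability
in [0, 1] and, on sentences small enough to enumerate, agrees with
exhaustive label-sequence enumeration to ~1e-15 (tested at 1e-9). A cheaper
product-of-token-marginals alternative is available via
`confidence_method="token_product"`; it underestimates correlated spans and
is not the default.

### Harmonization

Annotation sets from several models are merged by a confidence rule: spans
that intersect nothing from any other set are kept; within each **maximal
group of chain-overlapping spans** exactly the highest-confidence span
survives. Resolution over maximal groups (rather than pairwise) makes the
operation idempotent and its output non-overlapping by construction. Ties
are broken deterministically: earlier start, then longer span, then
lexicographically smaller model id.

## Preprocessing

Sentence splitting is rule-based: sentence-final punctuation followed by
whitespace and an uppercase letter or digit, with an editable exception
list (packaged text resource) for common abbreviations (`e.g.`, `et al.`,
`Fig.`, ...) and single-letter initials.

Tokenization first splits on whitespace and detaches sentence punctuation
(`,;:!?()[]{}"'`), then divides any token containing `/`, `-` or `.` so
each such symbol becomes its own single-character token — locants, stems
and substituents of systematic names then become separate observations.
One deliberate exemption: a `.` between two digits (`0.5`) is kept, since
splitting dose/quantity tokens destroys them and the rule targets chemical
names, not numbers. Tokenization is offset-exact and idempotent.

Linguistic attributes come through a pluggable tagger contract (lemma,
POS, chunk, dependency capabilities; a tab-separated exchange format for
external-process taggers). The packaged `FallbackTagger` is deterministic
and rule-based — closed-class word lists plus suffix heuristics for POS,
lowercasing lemmas, a simple NP/VP chunker — so the entire pipeline runs
with no external NLP tool. It does not emit dependencies, which is
consistent with the default feature set dropping the dependency group.

## Features

All features are `group=value` strings; groups can be disabled
independently, and extraction commutes with group removal (tested). The
default configuration is the empirically best one: all groups minus
dependency parsing and capitalization, with conjunctions rather than
windows for local context. Affix and n-gram lengths default to {2, 3, 4};
affix lengths mirror the stated n-gram lengths since they are not
specified separately. Counting features are binned (No/One/Two/ThreeOrMore
× Digit/Cap) following the `TwoDigit`/`TwoCap` naming convention.
Dictionary matching is case-insensitive after NFKC normalization, requires
token-boundary alignment (no substring noise), and resolves overlaps
leftmost-longest, emitting positional `LEXICON=B/I` features. Window
features copy neighbour lemma/POS/chunk values tagged with their offset;
conjunction features concatenate lemma (resp. POS) across a window with a
reserved `|` separator and the window identity in the feature name;
positions outside the sentence contribute `BOS`/`EOS` placeholders.
Windows and conjunctions are mutually exclusive by construction. Where
dependency features are enabled, both the dependency label and the head
token's lemma are emitted, since neither alone is obviously preferable.

## Post-processing

*Parentheses parity*: an annotation whose text contains an odd total count
of `()[]{}` is removed — a truncated chemical name.

*Abbreviation resolution* uses the classic character-matching definition
recognizer: parenthesized candidates of 2–10 characters, at most two
words, at least one letter, first character alphanumeric; the long form is
found by matching short-form characters right-to-left into at most
min(|SF|+5, 2·|SF|) preceding words, the first character anchored at a
word start. One chemistry adaptation: contracted abbreviations such as
`EtOH`/"ethanol" violate strict in-order matching (the `H` precedes the
`O` in the word), so when strict matching fails the single word
immediately before the parenthesis is accepted if it starts with the short
form's first letter and contains all its characters. If one form of a pair
is annotated the other is added (source `abbrev`, inheriting the
confidence so ranking stays meaningful — not a fixed constant); partially
covered forms are expanded to the span union; identical spans are merged
keeping the higher confidence.

*Exclusion list*: for every distinct lowercased predicted mention, TP
counts exact-span gold matches and FP the rest; the mention is excluded
iff ln((TP+0.5)/(FP+0.5)) < θ and FP ≥ k. Defaults θ = 0.3, k = 2. The
+0.5 Haldane smoothing makes zero-TP mentions scorable; natural log.
Threshold tuning partitions documents into 10 seeded folds, builds the
list on 9/10, measures ΔF1 on the held-out tenth, and picks the grid point
with the best mean ΔF1 (ties prefer higher θ, then higher k). Blind
length-based filtering is deliberately not provided — it trades large
recall losses for marginal precision.

Order of application: parentheses → abbreviations → exclusion list
(optional). The first two never remove correct structure the model
produced (the abbreviation stage never deletes annotations); the exclusion
stage only deletes and never modifies survivors.

## Evaluation

Matching modes: exact (both offsets), left (start), right (end), shared
(either), overlap (any intersection). Matching is one-to-one per document
section: exact pairs are matched first in every mode, then remaining
candidates greedily by earliest prediction start, then longest overlap —
the relaxed-mode tie handling is not fully standardized, so it is pinned
down deterministically here. Identical predicted spans are merged before
counting (a duplicated span should not count as an extra false positive).
Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean,
reported as percentages with half-up rounding at two decimals. CDI
evaluation intersects per-document mention-string sets. Class recall is
reported per gold class only (the tagger is trained on a single merged
class, so class precision is undefined). The iterative elimination
protocol retrains one model per candidate group removal per round, removes
the most beneficial group, and stops when nothing improves; the surface
token group is protected from removal.

The published benchmark (P, R, F) triples carried in
`evaluation.REPORTED_RESULTS` are used as an arithmetic consistency check
on the F1 formula. Since P and R are printed rounded to two decimals,
propagating that rounding through the harmonic mean can move F1 by up to
about 0.01, which is therefore the attainable consistency bound; most rows
agree to within 0.005, four only to 0.0052–0.0065.

## Synthetic corpus

The generator emulates the statistical shape the pipeline assumes:
templated title + abstract sentences where mention context is predictive
("treatment with X", "levels of X"), mention surfaces with class-typical
morphology — systematic names from a locant–substituent–core grammar with
optional parenthesized substituents, formulas from an element-symbol/count
grammar, trivial names from a ~200-entry packaged list, families as
pluralized stems, registry-style identifiers, coordinated systematic
fragments for the multiple class, and abbreviation definitions
(`long form (SHORT)`) from a pool whose pairs the definition recognizer
can find. Homograph trap terms (`lead`, `gold`, `iron`, `mercury`) are
planted both as annotated chemicals and as ordinary words so the
exclusion-list machinery has realistic targets. Gold offsets are exact by
construction; all output is deterministic given the seed. Defaults: 200
documents, mention count per document negative-binomial with mean 6 and
dispersion 0.3, abbreviation-definition rate 0.3 per document, 30% of
generated non-trivial surfaces added to the lexicon plus all trivial
names, element names and a few distractors.

What it does **not** emulate: real journal prose, rare or novel
nomenclature, tokenization ambiguity at the scale of real CHEMDNER text,
annotation-guideline edge cases, or realistic class frequencies. The
synthetic language is deliberately learnable — a 200-document training run
reaches near-perfect held-out F1 in seconds — so synthetic results
demonstrate that the machinery (features → CRF → harmonization →
post-processing → ranking) is implemented correctly, *not* that the tagger
would reach any particular F1 on real corpora, where the published
state of the art is in the high 80s.

`corrupt_predictions` derives simulated system output from gold with
controllable false-negative rate, trap-term false positives, and boundary
jitter snapped to adjacent word boundaries (so relaxed matching can
recover what exact matching loses); synthetic confidences overlap between
correct (0.6–0.99) and spurious (0.05–0.7) spans.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down experiments chosen to
exercise every code path while completing in minutes on one CPU: 200/50
train/test documents for end-to-end learnability, 20 short sentences for
the enumeration oracle (≤ 8 tokens, 3^T sequences scored exhaustively), 50
corruption runs for mode monotonicity, 1000 random set pairs for
harmonization, 10 seeds for recall recovery. Degenerate inputs are defined
everywhere: empty corpora raise, empty sentences are skipped, an
all-`O` decode yields an empty annotation set, zero-denominator precision
and recall are reported as 0, and an empty-gold/empty-prediction
evaluation is flagged. Ranking ties are deterministic (title before
abstract, then ascending start, then end); CDI deduplication is
case-sensitive exact-string, matching string-based document indexing
gold.

## Known limitations

- The fallback tagger's POS/chunk accuracy is far below a trained
  biomedical tagger; on real text, plug in a proper tagger through the
  contract for fidelity.
- The reader rejects overlapping gold spans; relax if a real corpus
  requires nested annotations.
- No entity normalization, no class assignment at decode time, no
  statistical significance machinery between runs.
- Exact reproduction of published corpus figures requires the licensed
  CHEMDNER corpus and is out of scope; the package validates against
  properties and scaled-down synthetic experiments instead.
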