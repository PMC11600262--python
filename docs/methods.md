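# Methods

This note documents the models, statistics, and design choices behind
`litreg`, a pipeline that turns biomedical abstracts into a directed,
provenance-weighted molecular-regulatory knowledge graph.

## Problem and pipeline

Given plain-text abstracts, the pipeline recognizes four kinds of
entity mentions — genes, signaling pathways, cancers, and biological
functions — extracts five kinds of directed relation between them
(Promotes, Inhibits, Upstream, Abbreviation, Function), fuses the two
predictions under entity-type constraints, and aggregates the
resulting triples into a knowledge graph that can be filtered by
relation type, edge frequency, and publication year, queried for
intermediary molecules, and annotated with expression-based
confidence.

Two learned components sit at the core and are trained
independently, per sentence:

1. a **named-entity tagger**: token embeddings → bidirectional RNN →
   linear-chain CRF over BIO tags;
2. a **relation extractor**: contextual token representations plus
   five learned relation-slot embeddings scored pairwise into a
   *unified interaction map*, trained with binary cross-entropy.

Everything downstream of the two models is deterministic.

## Tokenization and corpus model

Offsets are 0-based and half-open throughout; entity spans are token
intervals local to one sentence; relations are strictly
intra-sentential (entity mentions never cross sentence boundaries).
The tokenizer is rule-based and deterministic: whitespace-splitting
with leading/trailing punctuation split off as single-character
tokens, internal hyphens preserved (so "WNT-4" is one token), and
sentence boundaries at `[.!?]` followed by whitespace and an
uppercase letter, with a short abbreviation stoplist ("e.g.",
"et al.", "Fig.", ...). A rule-based segmenter keeps the whole
pipeline reproducible to the byte and needs no language resources at
run time.

The interchange format is JSONL, one document per line, with entity
spans as *global* token indices over the flattened document and
relations as indices into the entity list. The reader re-tokenizes
the text, so surfaces are always slices of the stored text, and
schema violations are reported with 1-based line numbers.

Ill-formed predicted BIO sequences (an `I-X` run with no opening
`B-X`) are repaired by promoting the first `I-X` to `B-X`: a lossless
repair that keeps evaluation well-defined no matter what a model
emits. In practice the tagger cannot produce such sequences because
decoding is masked (below); the repair path exists for foreign
predictions read from disk.

## Named-entity tagger

Per token, the input representation concatenates

* a trainable lookup-table embedding (default 32 dims, case-sensitive
  because case distinguishes gene aliases), with an `<unk>` row for
  unseen tokens, and
* fixed hashed character-trigram features (24 dims, CRC32 signed
  hashing, L2-normalized), which give morphological variants of a
  symbol nearby representations without any training.

A linear layer merges the two views (48 dims), a single-layer
bidirectional tanh RNN (32 hidden units per direction) provides
context, a linear map produces per-tag emission scores, and a
linear-chain CRF (9 tags = O plus B/I for four entity types) supplies
transition scores. Training minimizes the exact negative conditional
log-likelihood — log-partition by the forward algorithm minus the
gold path score — with per-sentence Adam steps (lr 0.01, 12 epochs by
default) and all gradients derived by hand (CRF gradients are the
posterior-minus-gold marginals from forward–backward;
backpropagation-through-time for the RNN). Finite-difference tests
pin every gradient.

Decoding is Viterbi under a *hard BIO mask*: transitions into `I-X`
from anything but `B-X`/`I-X`, and sequences starting at `I-X`, score
−∞. The mask guarantees well-formed spans regardless of training
quality; it is applied only at decode time so that training remains
a smooth unconstrained problem.

The embedding interface is a two-method contract (`dimension`,
`embed(tokens)`), so contextual embeddings from transformer models
can be plugged in without touching the tagger; the bundled providers
are deliberately desk-scale.

## Relation extractor

Each sentence of `L` tokens is scored as an `(L+5) × (L+5)` matrix:
the first `L` rows/columns are tokens, the last five are relation
slots in the fixed order Promotes, Inhibits, Upstream, Abbreviation,
Function. A gold triple, anchored at the *first token* of each
entity span (the head-token convention; full spans are restored at
integration), lights three cells:

* (subject head, object head) — entity–entity,
* (subject head, slot) — subject–relation,
* (slot, object head) — relation–object,

with row = slot and column = object fixed as the package's
convention for the relation–object cell. Decoding emits `(s, r, o)`
whenever all three cells clear the decision threshold τ (default 0.5,
configurable); the decoded set can only shrink as τ rises.

A triple set in which two triples share head tokens can produce a
cell union that decodes to a strict superset of the gold set — an
inherent ambiguity of the three-cell rule, not an implementation
defect. With distinct heads the map decodes losslessly, and the test
suite asserts exactly that dichotomy.

The scorer computes query/key projections of a shared representation
— lookup + character embeddings, linear merge, and the same BiRNN
architecture as the tagger — plus five learned slot embeddings, and
takes a scaled dot product through a sigmoid. The recurrent context
layer is essential, not decorative: a context-free bilinear scorer
over word embeddings cannot represent the map at all, because the
direction of a relation and the choice of predicate depend on the
verb, which lives at other positions in the sentence.

Training minimizes mean element-wise binary cross-entropy against
the gold map. Because positive cells are ~1% of the map, per-sentence
Adam steps oscillate; gradients are therefore averaged over
mini-batches of 8 sentences (lr 0.01, 20 epochs by default), which
fits the training set essentially exactly on the synthetic corpus.
Sentences longer than a configurable cap (default 80 tokens) are
skipped with a warning at both training and inference.

## Integration

Relation types between entities are contextually constrained — the
canonical example being that an abbreviation relation cannot hold
between a gene and a biological function. Integration anchors each
predicted head pair inside recognized entity spans (containment, not
exact match, since the extractor works at head granularity), restores
the full typed spans, and keeps the triple only when the (subject
label, predicate, object label) combination is allowed. The default
table: Promotes/Inhibits/Upstream require a gene or pathway subject
(any object type); Function requires gene/pathway → biological
function; Abbreviation requires identical labels. The table is total
over the 4 × 5 × 4 space and fully overridable from TSV. Integration
is a pure filter — it never invents a triple — and is idempotent.

## Knowledge graph

Aggregation normalizes mentions to node identifiers: gene surfaces
resolve case-insensitively through an NCBI gene_info-style synonym
table; unknown or ambiguous gene surfaces and all non-gene mentions
become their case-folded, whitespace-collapsed surface. An alias
claimed by two symbols is never guessed: the mention keeps its own
surface as a node and a warning is logged. Abbreviation triples do
not become edges; they extend a run-scoped copy of the synonym table
(alias → standard symbol), which is how abbreviations contribute to
node uniqueness. Support is deduplicated per (document, sentence) —
edge weight counts distinct supporting mentions, not publications —
and each support records (doc_id, year, sentence_index) as
provenance. Normalization-induced self-loops are dropped and logged.
Aggregation is order-invariant and conserves counts: total edge
weight equals the number of distinct non-self-loop supports.

Filters (predicate set, minimum weight, inclusive year range) compose
commutatively and return a new graph with orphaned nodes pruned; an
edge with undated support passes year filters by default. Path
queries enumerate simple directed paths through
Promotes/Inhibits/Upstream edges only (parallel edges collapsed to
the strongest), ranked by length ascending then bottleneck weight
descending, and report the interior nodes as candidate intermediary
molecules.

## Expression-based confidence

Regulatory edges whose endpoints both appear in a genes × samples
expression matrix gain the Pearson correlation of the two genes and a
qualitative band on |r| (weak < 0.3 ≤ moderate < 0.6 ≤ strong,
configurable); all other edges get an explicit no-data marker. The
matrix loader validates uniqueness, finiteness, and a minimum of
three samples, and performs no transformation — log-normalization is
the caller's responsibility.

Directional support uses a median-split rank-sum test: samples at or
below the split gene's median form the low group (ties to low, which
is deterministic for the even sample sizes typical of small cohorts),
and the test gene's values are compared between groups by
Mann–Whitney U (ties as ½). For combined n ≤ 20 the two-sided p-value
is exact, by full enumeration of all equal-content group assignments
(both tails, capped at 1); beyond that, a tie-corrected normal
approximation with continuity correction. The exact path is written
in-house because standard exact routines decline tied data; it is
cross-checked against independent enumeration and against
`scipy.stats.mannwhitneyu` on tie-free cases.

## Evaluation harness

Scoring is exact-match: a span counts only with exact boundaries and
label; a triple only with exact subject span, predicate, and object
span (direction included). Matching is one-to-one via multiset
intersection; counts are kept per class and pooled (micro-averaging).
Precision, recall, and F1 follow the standard definitions, with zero
denominators reported as 0 with a warning.

Binomial proportions carry Wilson score intervals
(z = Φ⁻¹(0.975) ≈ 1.959964). The Wilson interval was chosen because
it exactly reproduces, at two decimal places, the printed confidence
intervals of the published evaluation this harness mirrors; the
implementation is closed-form and cross-checked against
`statsmodels.proportion_confint(method="wilson")` in tests.

Paired method comparison uses the McNemar test on discordant counts:
an exact binomial (doubled smaller tail, capped at 1) below 25
discordant pairs, a continuity-corrected chi-square above; zero
discordance returns p = 1 with a warning.

## Synthetic corpus and expression generator

The generator emulates the shape of a curated abstract corpus:
2–5 templated sentences per document, covering all five predicates
with distinct trigger vocabularies, multi-token cancer and function
mentions, pathway subjects/objects, gene aliases (hyphenated and
case variants, used with probability 0.3), abbreviation-definition
sentences, and distractor sentences that mention entities without
relating them (so relation training sees true negatives). Defaults:
300 train / 100 test / 50 validation documents split by document,
30 genes (synthetic GENA symbols plus WNT4, STAT3, IGF2 so the
WNT4 → STAT3 → IGF2 intermediary demo works out of the box),
relation mix (0.30, 0.25, 0.15, 0.15, 0.15), distractor probability
0.25, years 2010–2024. Every alias used is emitted in the synonym
table, and gold spans are validated against the tokenizer at
generation time.

Expression matrices are multivariate-normal draws with a planted
correlation structure (default: an AR(1)-like WNT4–STAT3–IGF2 block
at ρ = 0.9, 14 samples — the scale of a small patient cohort); the
planted matrix is checked for positive semi-definiteness and sampled
through its eigendecomposition.

What passing tests on this corpus do **not** show: robustness to real
biomedical prose (negation, coordination, anaphora, nested entities,
cross-sentence relations), to unseen entity vocabularies, or to
annotation noise. The corpus is intentionally separable; held-out
scores near 100% certify the machinery, not real-world accuracy.

## Numerical choices and degenerate inputs

* CRF computations run in log space; masked Viterbi uses −1e30 as
  −∞ and errors if every path is masked.
* BCE probabilities are clamped at 1e-7 before logs.
* All randomness flows through `numpy.random.default_rng` seeds held
  in the config objects; training, generation, and prediction are
  bit-reproducible for a fixed seed.
* Empty corpora, zero-variance expression vectors, degenerate
  rank-sum groups, overlapping gold spans, unknown labels/predicates,
  and non-PSD planted correlation matrices all raise typed errors.
* Model checkpoints are numpy `.npz` archives with a JSON metadata
  block (vocabulary, config, tag/predicate inventory).

## Problem sizes used in validation

The acceptance script trains on the 300-document seed-1 corpus and
scores the 100 held-out documents; oracle checks use 100 random CRF
instances (L ≤ 5, T ≤ 9, exhaustive path enumeration), 200 random
interaction maps (L ≤ 10), full-permutation rank-sum enumeration at
n ≤ 10, all McNemar tables with b + c ≤ 12, and 100 expression
replicates at n = 50 per planted ρ ∈ {0, 0.5, 0.9}. These sizes keep
every oracle exhaustive (not sampled) while the whole script runs in
about a minute.

## Known limitations

* The bundled embedding providers are desk-scale; matching published
  extraction quality on real abstracts would require plugging in
  pretrained contextual embeddings through the provider interface.
* Coreference, negation/hedge detection, and cross-sentence relations
  are out of scope; relations are strictly intra-sentential.
* Species disambiguation is not attempted; the synonym table is the
  sole arbiter of gene identity.
* Edge confidence is correlation-based and per-matrix; it neither
  implies causation nor pools across cohorts.
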