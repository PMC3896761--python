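# Methods

## Task and model

Event trigger recognition is cast as per-token sequence labeling: for each
event type, every sentence is encoded with BIO labels over its gold trigger
spans and modeled by a linear-chain conditional random field

p(y | x, λ) = Z(x)⁻¹ · exp Σⱼ λⱼ Fⱼ(y, x),
Fⱼ(y, x) = Σᵢ fⱼ(yᵢ₋₁, yᵢ, x, i),

where each fⱼ is a state function (one indicator per observed
attribute/label pair) or a transition function (one per label pair).
Training maximizes the L2-regularized conditional log-likelihood with
L-BFGS; decoding is exact Viterbi. One independent model is trained per
event type, which lets a single span carry several trigger types (each
model tags it independently) and lets each type use its own feature set.

Why one-vs-all CRFs rather than one multi-class tagger: trigger types have
heterogeneous linguistic profiles, and a per-type model can adopt a feature
configuration (and model order) tuned to that profile alone.

### Higher model orders

An order-o chain, where each label depends on the o−1 previous labels, is
reduced to a first-order-equivalent chain by composing labels: position i
carries the concatenation `y[i-o+1]|…|y[i]` (shorter near the sequence
start). Two masks make the reduction exact rather than approximate:
a composite of k components is only valid at positions with exactly k
labels of history available, and a transition a→b is only valid when b's
history equals a's recent suffix. Both masks are applied inside the
partition function during training and inside Viterbi during decoding, so
the reduced model's distribution equals a native order-o chain's.
`lower_order` (keep each composite's last component) inverts the encoding.

### Hyperparameters

- `sigma2` (default 1.0): variance of the Gaussian prior; penalty
  ‖w‖²/(2σ²). Exposed because the right amount of regularization depends
  on corpus size.
- `max_iter` (default 200) and `tol` (1e-5): L-BFGS stopping. Training is
  deterministic given fixed data order; attribute and label alphabets are
  sorted so the result is also independent of feature-string order.
- Degenerate inputs: a corpus with zero positive spans trains (and logs a
  warning); the resulting single-label model predicts all-O.

## Feature catalogue

Nine families, each emitting `KEY=value` strings into a per-token multimap;
every key belongs to exactly one family, which is what makes per-model
filtering of a shared extraction possible.

| family | keys | content |
|---|---|---|
| token | W, LEMMA, POS, CHUNK | surface form, lemma, POS tag, BIO chunk tag |
| orthographic | CAP, COUNT_UPPER, COUNT_DIGIT, LENGTH, SYMBOL | capitalization tags (InitUpp, MixCase, ...), character counts, symbol occurrence |
| morphological | PREFIX2-4, SUFFIX2-4, CHARNGRAM_n, SHAPE | affixes, character n-grams, word shape (A/a/1/#) |
| sentence | SENT_SIZE | token-count bin: <15, [15,20), ..., ≥40 (seven bins, lower-inclusive) |
| concepts | CONCEPT, CONCEPT_NAME, CONCEPT_&lt;TYPE&gt;_HEAD, NUM_&lt;TYPE&gt; | tags on covered tokens; names, heads and per-type counts on every token of the sentence |
| dictionary | Trigger | event type of any covering dictionary match |
| modifier | SUBJ_OF_VERB, OBJ_OF_VERB, MODIFIES_NOUN, MODIFIER | lemmas read off the directed edge metadata and POS |
| dependency_edge | IN_DEP_*, OUT_DEP_* | label, lemma, POS and chunk of the other endpoint of each incident edge |
| shortest_path | SP_*, SPDistance | features of the path to the closest concept token |

Context modes (applied after the families): local windows copy neighbor
token/lemma/POS/chunk values at offsets −3…+1; dependency windows copy
lemma/POS/chunk of all tokens within a hop limit (≤3); conjunctions join
lemma/POS values of offset pairs {−3,−1},{−2,−1},{−1,0},{−1,1},{0,1}
(e.g. `interferon@-1_&_factor@1`).

Design decisions worth recording:

- **Path pairing.** Dependency-path features are emitted for the
  token-to-closest-concept pair only (plus per-edge IN/OUT features); no
  other token pairing is defined by the method, and triggers are
  characterized precisely by their relation to nearby concept mentions.
  Ties on hop count break toward the smallest target token index; among
  equal-length paths the lexicographically smallest vertex sequence is
  returned (BFS with a greedy smallest-successor reconstruction), so
  features are reproducible.
- **IN/OUT orientation.** The dependency graph is undirected for path
  queries; head→dependent direction is kept as edge metadata. "Input"
  dependencies of a token are the edges arriving from its dependents and
  "output" the edge toward its head — a single module switch
  (`features._IN_MEANS_HEAD`), calibrated once against the worked-example
  sentence and isolated in case a differently-oriented parser is used.
- **Concept head.** The head token of a concept mention is its first
  token; linguistic head finding is out of scope and the first token
  matches the worked example ("interferon" for "interferon regulatory
  factor 4").
- **Affix lengths** are fixed at 2–4; character n-gram sizes, hop limits
  and vertex information (lemma/token/POS/chunk) are configuration
  parameters with defaults {2,3}, 3, lemma before optimization.
- Numeric values (counts, SPDistance) are emitted as categorical strings,
  consistent with an indicator-feature CRF.

### Union-then-filter extraction

Annotating with several models would naively re-extract features per
model. Instead the union of all model configurations (families unioned,
n-gram sets unioned, hop limits maxed, all needed vertex types) is
extracted once per sentence; each model's exact feature strings are then
recovered by key-based filtering (parameter-bearing keys encode their
n-gram size and vertex type; tokens whose SPDistance exceeds a model's hop
limit drop their path features), and the model's own context mode is
applied after filtering — context modes are not unioned. Filter
equivalence (filtered union extraction ≡ direct extraction, byte for byte)
is the module's central tested property.

## Dictionary matching and post-processing

Dictionary tagging compiles case-folded names into an Aho–Corasick
automaton; hits count only when both ends coincide with token boundaries
("exact matching" read as whole-token matching), and hits nested inside a
longer hit of the same dictionary are dropped. Two rule filters prune
predictions: spans whose text has an odd count of round, square or curly
brackets (counted per family — stricter than pooled counting, and any odd
family already indicates a truncated span), and triggers in sentences with
no concept annotation (events need participants). Filters only remove,
never mutate, and are idempotent.

## Greedy per-type optimization

The search space is (feature families F, model orders O, context modes C,
n-gram size sets N, hop limits H, vertex types V). For each event type:

1. documents are randomly split (default 75/25, document-level to avoid
   leakage between sentences of one abstract; seeded);
2. a greedy forward pass walks F in catalogue order (token → orthographic
   → morphological → sentence → concepts → dictionary → modifier →
   dependency-edge → shortest-path), keeping a family only on a *strict*
   dev-F1 improvement — ties reject, preferring the simpler model;
3. the best context mode is selected (default none), then n-gram sizes,
   hop limits and vertex types are refined for the families that survived
   step 2; rejected families are skipped entirely;
4. every candidate is trained once per order in O and scored by
   exact-match micro-F1 on the dev split (raw decoding, no
   post-processing — the filters belong to the annotation pipeline); F1
   ties between orders go to the lowest order;
5. the final configuration carries the best order of the last accepted
   trial, and the final model is retrained on the *complete* corpus.

The accepted-trial F1 sequence is non-decreasing by construction, the
whole search is reproducible under a fixed seed, and a tab-separated audit
log records every trial. No backtracking is performed: later refinements
never revisit the family decisions of step 2.

## Evaluation

Exact span matching only (both boundaries must match; most real triggers
are single tokens, so fuzzy matching is deliberately not offered),
one-to-one per type. Precision, recall and F1 are micro-averaged: TP/FP/FN
counts pool over documents and over the requested types before the
formulas apply; empty denominators yield 0; scores are reported on a 0–100
scale. Grouping presets follow the standard simple / binding / regulation
partition of the nine GENIA trigger types.

## Synthetic corpora: what they emulate and what they do not

`FixtureSpec`/`generate_corpus` build seeded toy corpora: short sentences
in which trigger-lexicon words appear either in a trigger context
(followed by "of" plus a concept mention; gold-labeled) or, at the noise
rate, in a non-trigger context; every trigger's sentence contains a
concept annotation; parses are random connected trees over a small
GDep-like label set (SUB, OBJ, NMOD, PMOD, VMOD). Defaults — 60 documents
× 5 sentences (~300 sentences), two event types, noise rate 0.2 — are the
study conditions used by the behavior-recovery tests.

These corpora make trigger-hood *learnable but not trivial*: lexical
identity alone is insufficient at noise > 0, and context features resolve
the ambiguity. They do **not** emulate real biomedical language:
vocabulary is tiny, parses are random rather than grammatical, triggers
are single tokens, and type frequencies are uniform. Passing the recovery
tests therefore demonstrates that the machinery (features → CRF →
optimizer) recovers a planted signal under noise, not that any particular
corpus-level score is attainable on real text.

The worked-example sentence is frozen in full (tokens, offsets, lemmas,
POS, chunks, 13 dependency edges). Only the fragments the documentation
prints are calibration-constrained; the remaining edges are arbitrary
frozen choices and tests rely only on the printed fragments.

## Numerical choices

- Forward–backward runs batched over padded sequences in log space;
  invalid states/transitions carry a large negative constant (−1e30)
  rather than −inf so gradients stay NaN-free.
- Viterbi ties resolve to the lowest label index (labels sorted), making
  decoding deterministic.
- Model bundles serialize weights and alphabets as JSON; Python's float
  round-trip is exact, so save/load reproduces predictions bit-for-bit.
- A1 output continues trigger ids after the highest concept id; the
  within-field dictionary name separator is `|`.

## Known limitations

- No semi-supervised training, no event-argument extraction, no A2 files.
- The greedy search is order-dependent (the family order is configurable)
  and does not backtrack; it finds good, not optimal, configurations.
- Higher-order training cost grows with the composite-label alphabet;
  orders above 3 are legal but rarely useful.
- The CoNLL dialect requires document-absolute offsets; converters from
  other tokenizations must supply them.
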