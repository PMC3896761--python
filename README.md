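# trigrec

Biomedical event **trigger recognition** with per-event-type optimized
linear-chain CRFs.

Biomolecular events in the literature (gene expression, binding,
regulation, ...) are anchored to a *trigger*: the word or chunk of text that
signals the event and serves as its predicate ("expression" for a
Gene_expression event). Finding triggers is the first step of event
extraction, and it is hard: the same word may or may not be a trigger
depending on context, one span can trigger several event types at once, and
different event types have very different linguistic profiles.

`trigrec` addresses this by training **one conditional random field per
event type** over BIO-encoded sentences,

&nbsp;&nbsp;&nbsp;&nbsp; p(y | x, λ) = Z(x)⁻¹ · exp Σⱼ λⱼ Fⱼ(y, x),

with a rich, switchable feature catalogue — token/lemma/POS/chunk,
orthographic and morphological shape, sentence length, concept annotations,
trigger dictionaries, grammatical-role modifiers, input/output dependency
edges, and shortest dependency paths to the closest concept mention — plus
three local-context modes (windows, dependency windows, conjunctions).
A **greedy search** then optimizes, per event type, the active feature
families, the context mode, n-gram sizes, dependency hop limits, vertex
information and the CRF model order o (orders > 1 are realized by a
composite-label reduction to a first-order chain), always scoring candidate
configurations by exact-match micro-averaged F1 on a held-out document
split. At annotation time, features are extracted **once** per sentence
with the union of all model configurations and filtered per model, so
multi-model tagging stays cheap; two rule filters (odd bracket counts,
concept-free sentences) prune false positives.

The tool consumes pre-parsed input (sentence splitting, tokenization,
lemmas, POS, chunks and dependency parses are produced upstream, e.g. by a
GDep-style parser) and reads/writes BioNLP standoff formats.

## Input formats

Each corpus directory holds, per document: `<id>.txt` (raw UTF-8 text),
`<id>.conll` (one token per line, blank line between sentences, nine
tab-separated columns: sentence-internal index, token, start, end, lemma,
POS, BIO chunk tag, 1-based head index with 0 = root, dependency label;
offsets are document-absolute, end-exclusive), `<id>.a1` (concept
annotations, BioNLP A1 standoff) and optionally `<id>.trig.a1` (gold
triggers, same layout). Trigger dictionaries are TSV files
(`identifier<TAB>name|name|...`).

## Worked example

The library ships a frozen, fully parsed example sentence
("Down-regulation of interferon regulatory factor 4 gene expression in
leukemic cells." with a Protein annotation over "interferon regulatory
factor 4"):

```python
>>> from trigrec import worked_example_fixture, closest_concept_path
>>> from trigrec.features import ModelConfiguration, extract
>>> sent = worked_example_fixture().sentences[0]
>>> reg = sent.token_at("regulation")
>>> path = closest_concept_path(sent, reg.index)
>>> path.hops, path.edge_labels
(3, ['NMOD', 'PMOD', 'NMOD'])
>>> cfg = ModelConfiguration(event_type="Gene_expression",
...                          active_features={"shortest_path"})
>>> sorted(f for f in extract(sent, cfg)[reg.index] if "NGRAM" not in f)
['SPDistance=3', 'SP_EDGE_PATH=NMOD-PMOD-NMOD', 'SP_EDGE_TYPE=NMOD_3',
 'SP_VERTEX_PATH_LEMMA=regulation-of-expression-4']
```

The shortest dependency path from "regulation" to the closest concept runs
regulation→of→expression→4 (3 hops), and the extractor emits exactly the
path features above: the token is three hops from a protein mention, a
strong hint that it triggers a regulation event.

A full command-line round trip on a generated toy corpus:

```sh
trigrec fixtures corpus --seed 9 --docs 40
cat > config.yaml <<EOF
corpus: corpus
types: [Gene_expression, Positive_regulation]
space:
  families: [token, orthographic, concepts]
  orders: [1]
  contexts: [none, window]
split_ratio: 0.75
seed: 7
output: optimized
models: models
EOF
trigrec optimize config.yaml     # greedy per-type configuration search
trigrec train config.yaml        # final models on the full corpus
trigrec annotate corpus --models models --out annotated
trigrec evaluate corpus annotated
```

The optimizer's audit log (`optimized/trials.tsv`) shows the greedy pass;
for this corpus and seed it prints:

```
type	step	candidate	per_order_f1	best_order	best_f1	accepted
Gene_expression	feature	token	1:85.000	1	85.000	1
Gene_expression	feature	orthographic	1:85.000	1	85.000	0
Gene_expression	feature	concepts	1:82.051	1	82.051	0
Gene_expression	context	window	1:100.000	1	100.000	1
...
```

Token features alone reach dev F1 85.0 and are kept; orthographic features
tie (ties reject, preferring the simpler model); adding the local-window
context resolves the remaining trigger/non-trigger ambiguity (noise words
are distinguishable only by their right neighbor) and is accepted at F1
100.0. `trigrec evaluate` then reports exact-match micro-averaged
precision/recall/F1 per type, per group and in total:

```
type                      P       R      F1
Gene_expression      100.00  100.00  100.00
Positive_regulation  100.00  100.00  100.00
...
TOTAL                100.00  100.00  100.00
```

(The final models see the whole toy corpus, so self-annotation is perfect;
held-out scores during optimization are the honest numbers.)

## Benchmarking on a real corpus

The headline literature scores for this task come from the BioNLP 2009
GENIA shared-task corpus, which must be downloaded separately and
preprocessed into the formats above; a full optimization over all nine
event types, orders 1–3 and every feature family is a multi-hour run. The
same `optimize` / `train` / `annotate` / `evaluate` workflow above is the
benchmark harness: point `corpus:` at the converted corpus, list the nine
trigger types, and widen the space (all families, `orders: [1, 2, 3]`,
contexts, `ngram_sets`, `hops: [2, 3]`, vertex types). These corpus scores
are intentionally not part of the test suite.

## Layout

- `trigrec.core` — sentences, tokens, chunks, dependency graphs with
  shortest-path queries, nesting-aware annotation trees
- `trigrec.io_standoff` — text + CoNLL-dialect reader/writer, A1 standoff,
  TSV dictionaries, JSON/XML output
- `trigrec.features` — the feature catalogue, context modes,
  `ModelConfiguration`, union-then-filter extraction
- `trigrec.matching` — Aho–Corasick dictionary tagging and the two
  post-processing filters
- `trigrec.crf` — BIO encoding, the order-raising reduction, the
  linear-chain CRF estimator, per-type trigger models, corpus annotation
- `trigrec.optimizer` — dataset split, per-order trial training, the
  greedy search, finalization
- `trigrec.evaluation` — exact-match matching, micro-averaged P/R/F1,
  reports
- `trigrec.fixtures` — the worked-example document and seeded synthetic
  corpora
- `trigrec.cli` — the `trigrec` command

See `docs/methods.md` for modeling details and design decisions.
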