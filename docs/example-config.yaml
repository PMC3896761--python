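# Example configuration for `trigrec optimize` / `trigrec train`.
# Paths are resolved relative to the working directory.

corpus: corpus            # directory of <id>.txt/.conll/.a1/.trig.a1 files
types:                    # event types to model (need gold triggers)
  - Gene_expression
  - Positive_regulation

space:                    # optimization space (all fields optional)
  families: [token, orthographic, morphological, sentence, concepts,
             dictionary, modifier, dependency_edge, shortest_path]
  orders: [1, 2, 3]
  contexts: [none, window, dependency_window, conjunctions]
  ngram_sets: [[2, 3, 4], [2, 3], [3, 4]]
  hops: [2, 3]
  vertex_types: [lemma, token, pos, chunk]

split_ratio: 0.75         # train/dev document split for optimization
seed: 7                   # split seed; fixes the whole search
sigma2: 1.0               # CRF L2 prior variance
max_iter: 200             # L-BFGS iteration cap

dictionaries: []          # optional: [{type: Gene_expression, path: ge.tsv}]
output: optimized         # per-type *.config.json + trials.tsv
models: models            # *.model.json bundles written by `train`
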