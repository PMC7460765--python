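# chemnmt

Machine translation of chemical nomenclature between English and Chinese.

Chemical names are the lingua franca of chemistry literature, patents and
databases, and English and Chinese are the two most used nomenclature
languages.  Translating names between them is harder than word-for-word
substitution: Chinese chemical names carry no word boundaries (乙酸乙酯 has
no spaces), ester names reverse word order between the languages
("ethyl acetate" puts the alkyl group first, 乙酸乙酯 the acid), and suffix
translation is context-dependent (the hydroxyl "ol" becomes 醇 on an
aliphatic parent but 酚 on an aromatic ring: "methanol" → 甲醇, yet
"benzene-1,2,4-triol" → 苯-1,2,4-三酚).  Rule-based translators need
expert-curated rule sets and fail outright on names they cannot segment;
character-level neural translators learn these regularities from parallel
corpora and always produce an output for in-vocabulary input.

This package is for practitioners who want to train, compare and evaluate
both approaches:

* **`chemnmt.corpus`** — parallel-corpus data model: TSV I/O,
  deduplication (merging alternative translations), deterministic 80/20
  splitting, character vocabularies, and the integer tensor encoding for
  teacher-forced training.
* **`chemnmt.neural_models`** — two character-level seq2seq translators,
  built on a small in-package numpy autodiff engine:
  an **LSTM encoder–decoder** (the encoder's two final state vectors, each
  of width `latent_dim`, initialise the decoder, which is trained by
  teacher forcing on the target sequence offset by one step) and a
  **CNN encoder–decoder with attention** (3 encoder convolutions,
  3 causal target-side convolutions, scaled dot-product attention,
  2 causal output convolutions).  Greedy arg-max decoding; training
  defaults follow the reference regime (batch 64, 100 epochs, latent 256).
* **`chemnmt.rule_translator`** — the three-stage rule-based baseline:
  greedy longest-match **disassembly**, context-sensitive fragment
  **translation**, template-driven **reassembly**; rule sets are editable
  YAML, and a demonstration rule set ships for both directions.
* **`chemnmt.synth_nomenclature`** — a seeded toy-grammar generator of
  paired English/Chinese names exhibiting all of the phenomena above, so
  every experiment in this README runs without external data.
* **`chemnmt.evaluation`** — the metric suite: success rate, string
  matching accuracy (exact match against the primary reference), data
  matching accuracy (match against primary-plus-alternatives), stratified
  reports (naming system; Chinese-name length with the 6-character
  demarcation) and blinded spot-check sampling.

Formally, both neural models factorise the translation probability
character by character,

    p(y | x) = ∏_t p(y_t | y_<t, x),

train by teacher forcing (minimise masked cross-entropy of y_t given the
reference prefix) and decode greedily (ŷ_t = argmax of the per-step
distribution until the end symbol).  The evaluation metrics over a result
set R against references with accepted translation sets A(x) ⊇ {primary}:

    success        = |{r ∈ R : output produced}| / |R|
    string match   = |{r : output = primary}|   / |R|
    data match     = |{r : output ∈ A(x)}|      / |R|

so string match ≤ data match ≤ success rate always, with failures counted
in every denominator.

## Worked example

```sh
# 1. generate a 3,000-pair synthetic En→Ch corpus
chemnmt generate --n 3000 --seed 1 --out corpus.tsv

# 2. train an LSTM translator (desk-scale settings)
chemnmt train corpus.tsv --epochs 30 --latent-dim 128 --seed 1 --out ckpt/

# 3. translate the baseline fixtures
printf 'ethyl acetate\nmethanol\nbenzene-1,2,4-triol\n' > names.txt
chemnmt translate names.txt --checkpoint ckpt/ --out out.tsv
chemnmt baseline-translate names.txt --out rule_out.tsv
cat rule_out.tsv
```

The baseline output shows all three names translated with the packaged
demo rules:

```
ethyl acetate	乙酸乙酯	1	none
methanol	甲醇	1	none
benzene-1,2,4-triol	苯-1,2,4-三酚	1	none
```

Evaluating a trained LSTM on the 600-pair held-out split of the corpus
above prints (via `chemnmt evaluate` or the library API):

```
Success Rate                100.00%  (n=600)
String Matching Accuracy     99.83%  (n=600)
Data Matching Accuracy       99.83%  (n=600)
```

Success rate is 100% because every held-out name is composed of
characters seen in training — a neural translator only refuses on
out-of-vocabulary characters, which it reports as a failure value, never
an exception.  String matching counts exact agreement with the primary
reference; on a real corpus with one-to-many translations, data matching
is strictly higher.

To score a real corpus instead, place a UTF-8 TSV of
`source<TAB>target[<TAB>alternatives...][<TAB>tag]` under `data/` and
point the same commands at it; the full-corpus statistics checks in the
test suite pick up `data/en2ch.tsv` and `data/ch2en.tsv` automatically.

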