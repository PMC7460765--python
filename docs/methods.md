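# Methods

## Problem setting

Chemical nomenclature translation between English and Chinese is treated
as character-level sequence transduction.  Both languages name the same
molecular structures, but the surface strings differ in ways that break
word-aligned translation: Chinese names are unsegmented character runs;
ester constructions reverse constituent order between the languages;
suffix choice is context-dependent (醇 vs 酚 for hydroxyl, depending on
whether the parent is aromatic); and one name frequently admits several
accepted renderings in the other language.  The package implements two
neural translators, a rule-based baseline, and the exact-match evaluation
conventions appropriate to names (where near-misses are simply wrong).

## Neural models

Both translators model p(y|x) = ∏ₜ p(yₜ|y₍<t₎, x) over characters and are
trained by teacher forcing: the decoder consumes the reference target
prefixed with a start symbol and predicts the same sequence offset one
step, ending in an end symbol.  The offset invariant
(`decoder_input[t+1] == decoder_target[t]`) is asserted on every batch.

**LSTM encoder–decoder.**  A single-layer LSTM encoder reads the source
embedding sequence and emits its final hidden and cell vectors (each of
width `latent_dim`); a single-layer LSTM decoder starts from those states
and produces a softmax over target characters at each step.  Source
padding is handled by freezing a row's state once its true length is
passed, so the handed-over state is the state at the last real character.
Gate order is (input, forget, candidate, output) with forget-gate bias
initialised to 1.

**CNN encoder–decoder with attention.**  Three 1-D convolutions
(kernel 3, same padding, ReLU) encode the source; three causal
convolutions (left-padded, so step t sees steps ≤ t only) encode the
offset target; scaled dot-product attention (queries from the target
stack, keys/values from the encoder, pad positions masked) produces a
per-step context; the concatenated stream passes through two further
causal convolutions and a linear head.  Convolutions are
translation-equivariant, so learned positional embeddings (tables of 256
positions) are added to both embedding streams — without them the model
cannot reliably distinguish names differing only in a locant digit.
No residual connections or pooling are used.  Causality is verified by
perturbation: changing the decoder input at step t moves no output before
step t (tolerance 1e-6; in practice the untouched outputs are bit-equal).

**Training.**  Adam (lr 1e-3) on per-character cross-entropy with pad
positions masked, global gradient-norm clipping at 5.  One seed drives
initialisation, shuffling and any internal validation split.  Determinism
is statistical, not bit-level, across platforms (BLAS kernels differ);
on one machine, equal seeds give equal runs.  Defaults follow the
reference full-corpus regime — batch 64, 100 epochs, latent width 256 —
while the desk-scale experiments in the test suite and acceptance script
use latent 128 with 30 epochs (LSTM) and 45 epochs (CNN), sizes chosen so
the whole pipeline trains in minutes on one CPU.  The character
representation is a learned embedding of width `latent_dim` for both
architectures.

**Inference.**  Greedy arg-max decoding from the start symbol, stopping
at the end symbol or at `max_output_len` (default: longest training
target + 10, which guarantees termination).  The LSTM carries its state
step by step; the CNN re-runs its causal stack over the growing prefix.
Beam search is deliberately out of scope: greedy decoding keeps the
success-rate semantics trivial (any in-vocabulary input yields exactly
one output).  An out-of-vocabulary character produces a failure *value*
(`failure_reason="oov_character"`), never an exception, so success rate
is computable from results alone.

**Checkpoints** store the vocabulary (JSON), configuration (JSON),
parameters (npz) and per-epoch history (CSV); reloading is
prediction-identical because parameters are stored exactly (float32).

## The autodiff engine

The models run on a small in-package reverse-mode automatic
differentiation engine over numpy arrays (`chemnmt._autodiff`): a tape of
operation nodes with closures accumulating gradients, covering dense
algebra, pointwise nonlinearities, embedding lookup with scatter-add
gradients, im2col-based 1-D convolution, masked softmax and fused softmax
cross-entropy.  Gradients of the composite operations are checked against
central finite differences in the test suite.  All computation is
float32.

## Corpus conventions

All strings are normalized to Unicode NFC and trimmed on ingestion, so
full-width punctuation and combining marks compare stably.  Deduplication
keys on (source, target) and merges alternative translations of dropped
duplicates into the surviving record, preserving the corpus's one-to-many
information.  Character vocabularies are sorted by code point with the
three reserved symbols (pad, start, end — private-use code points that
cannot occur in chemical names) at the final indices, making model shapes
a reproducible function of corpus content.  The 20% held-out partition
(exactly `round(n·fraction)` pairs, a pure function of corpus, fraction
and seed) doubles as the test set.

## Rule-based baseline

Disassembly, fragment translation, reassembly — each stage driven by an
editable YAML rule set:

1. *Segmentation* is greedy longest-match, leftmost-first, with no
   backtracking; length ties between roles are broken by declaration
   order.  Locant runs (digits and commas) are matched built-in.  An
   unmatched position yields an uncovered segmentation — a value, so the
   per-stage failure statistics remain computable.  When segmentation
   covers, the fragments concatenate exactly to the input.
2. *Translation* looks fragments up by (text, role, context), with
   context precedence ester → aromatic → default.  Aromatic context is
   triggered by any declared aromatic parent in the name; ester context
   by any declared trigger fragment (acyl suffixes, the ester marker 酯).
   This reproduces 醇/酚 selection and the ester reading of alkyl groups
   without a structure model.
3. *Reassembly* applies the first template whose role-sequence pattern
   matches the non-punctuation fragments (templates reorder, e.g. the
   acyl/alkyl swap between "ethyl acetate" and 乙酸乙酯, and supply
   literal separators); otherwise fragments are emitted in input order,
   with separators coming from the fragment dictionary itself.

Failures are three-valued (segmentation / dictionary / none) so
evaluation can attribute error stages.  The packaged demo rule sets cover
exactly the toy grammar below — they demonstrate the architecture and are
not a production rule set; accuracy figures obtained with them say
nothing about any external rule-based tool.

## Synthetic nomenclature generator

The generator emulates the structure of a curated bilingual name corpus
with a toy grammar of ~40 morphemes: ten chain stems (meth…dec ↔ 甲…癸),
four halogens, benzene, suffixes for alkanes/alcohols/amines/acids/
esters/diols, di/tri multipliers, and locants.  Production families and
default mixture: alkanes 0.27 (plain, substituted, multi-substituted),
alcohols 0.20 (plain, positional, substituted), amines 0.015, acids
0.065, esters 0.36 (plain, inverted CAS comma form with probability 0.15,
halo-substituted), aromatic polyols 0.01, diols 0.08.  The weights favour
the families with large locant combinatorics so that 3,000 unique pairs
can be drawn (total grammar capacity is several thousand strings);
rejection of duplicate draws makes realised fractions deviate from the
configured mixture by a point or two, which the manifest records.

Generated pairs exhibit: ester order reversal, aromatic 酚 selection,
locants copied verbatim between languages, boundary-free Chinese, and —
with probability 0.10 where the production admits a variant — an
alternative accepted translation (e.g. 乙酸乙基酯 for 乙酸乙酯), which
makes string-match and data-match measurably diverge.  Naming-system tags
are IUPAC except for the inverted comma esters (CAS).

What the generator does **not** emulate: trivial natural-product names,
transliterations, nested substituents, stereodescriptors, the long-tail
character inventory of real Chinese corpora (a real corpus has ~2,000
unique Chinese characters; the toy grammar ~35), or chemically valid
locants.  Passing tests on generator output therefore demonstrate the
*mechanics* — teacher forcing, causality, decoding, metric algebra, rule
staging — and desk-scale learnability, not expected accuracy on real
nomenclature.

## Evaluation conventions

Accuracy denominators include failed translations (a failure can never
match), which keeps metrics comparable across systems with different
success rates; every report carries a note stating this convention.
String comparison is exact after NFC normalization and outer trimming,
case-sensitive.  Chinese name length counts *all* characters including
locant digits and punctuation, with 6 as the demarcation between short
and long names.  Spot-check sampling is uniform without replacement,
deterministic in its seed, and blinded: system identity goes to a
separate key table.  Running-time comparisons are excluded from reports
(hardware-dependent).

## Design decisions taken where the design was open

* Greedy decoding rather than beam search; dot-product attention with
  kernel-3 convolutions as the minimal standard realisation of the
  convolutional architecture's layer counts.
* Reversing a corpus (source↔target swap) emits a warning: name
  translation is not symmetric, and a reversed corpus is a fallback, not
  a substitute for a natively compiled one.
* The rule segmenter treats spaces, hyphens and commas as lexicon
  fragments inside one uniform longest-match scan (rather than
  pre-splitting English tokens); this keeps the concatenation invariant
  exact in both languages with one code path.
* Identity-order reassembly joins fragments without inserted separators;
  any needed space is part of a dictionary translation or template
  literal.  This is what the bilingual data demands (English hyphenated
  names contain no spaces either).
* `train_to_accuracy` restarts optimiser state between chunks; the fresh
  Adam moments act as a plateau-escape kick on tiny memorization corpora.

## Known limitations

* The CNN needs noticeably more optimisation steps than the LSTM to reach
  the same exact-match level at desk scale (45 vs 30 epochs here); at
  matched epochs its held-out accuracy is lower.
* Single-layer recurrent encoder/decoder only; no dropout or other
  regularisation (unnecessary at the scales exercised here).
* The demo rule sets cover the toy grammar exactly and nothing else, by
  construction; real nomenclature requires expert-curated rule sets.
* No GPU path; the numpy engine is single-threaded apart from BLAS.
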