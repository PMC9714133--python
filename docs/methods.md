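# Methods

## Problem setting

`cmedner` performs named-entity recognition on Chinese clinical narrative
text (electronic medical records) at the character level. Chinese EMR text
has no word boundaries and word segmenters trained on general text perform
poorly on clinical jargon, so each character is labeled directly with a
BIO tag: `B-t` begins an entity of type `t`, `I-t` continues it, `O` marks
everything else. Entity types are corpus-specific (e.g. BODY, TREATMENT,
SIGNS, CHECK, DISEASE); the tag scheme is therefore user-supplied, never
hard-coded. Offsets are 0-based and half-open everywhere.

## Model

The tagger is a hybrid network with four stages.

**1. Character embedding.** Each sentence is wrapped as
`[CLS] c_1 … c_n [SEP]`, right-truncated to `max_len` positions, and every
position is mapped to a vector of width `t`. Two encoders implement this
contract interchangeably: a trainable in-package embedding table built
from the training corpus (the default; no downloads), and an adapter
protocol for an external pretrained contextual encoder (a BERT-family
model for Chinese biomedical text; typically `t = 768`). CLS, SEP and PAD
positions carry embeddings but are masked out of CRF scoring, decoding and
evaluation — special positions never receive entity tags.

**2. Parallel feature extraction.** Two extractors read the embedded
sentence simultaneously:

* a **BiLSTM**: forward and backward passes with the standard gate
  equations (logistic sigmoid gates, Hadamard products,
  `h_t = o_t ⊙ tanh(c_t)`), hidden width `lstm_dim` per direction,
  zero initial states, per-position output `[h_fwd; h_bwd]` of width
  `2·lstm_dim`. State updates are gated by the padding mask so the
  recurrence freezes across padded positions, and outputs at padded
  positions are exactly zero.
* a **CNN bank**: 1-D convolutions of odd widths (default {1, 3, 5}) with
  same-length zero padding, ReLU, and a per-position channelwise max
  across kernel widths. Pooling preserves the position axis — a global
  max-pool would destroy the alignment needed for fusion with the BiLSTM
  path and for per-position CRF emissions.

**3. Fusion and multihead self-attention.** Both paths are linearly
projected to a common width `z` (default `2·lstm_dim = 200`) and summed
position-wise (project-then-add, not concatenation). One multihead
scaled-dot-product self-attention stage follows:

    head_i = softmax( (X W_i^Q)(X W_i^K)^T / sqrt(d_k) ) · X W_i^V
    MHA(X) = [head_1; …; head_h] W^O

with `d_k = z` the model width (the per-head projections are
`z × z/h`, and the score scale is the square root of the model width,
matching the convention in which the projections are rectangular).
Masked keys receive an additive −1e9 before the softmax and hence exactly
zero weight after it (the exponential underflows), so each attention row
is a distribution over the unmasked keys.

The model wires the attention stage with a **residual connection**
(`x + MHA(x)`). This is a deliberate design choice: at initialization the
projected queries and keys are small, attention is near-uniform, and a
pure `MHA(x)` output is approximately the same masked-mean vector at every
position — position-specific information then has to be recovered by
slowly sharpening the attention map, which measurably stalls training
(the overfit benchmark plateaus below F1 50 without the residual and
reaches 100 with it). The attention operation itself is unchanged; the
residual only affects how the trainer composes stages.

**4. CRF decoding.** A linear-chain CRF scores a tag sequence as

    score(X, y) = Σ_{i=0..n} A[y_i, y_{i+1}] + Σ_{i=1..n} P[i, y_i]

with emissions `P` (a linear projection of the attended features, width =
number of labels) and transitions `A` over the label set augmented with
START (`y_0`) and STOP (`y_{n+1}`). Training minimizes the negative
log-likelihood `−Σ log P(y|X)` with `P(y|X) = exp(score)/Z(X)`; the
log-partition `Z` is computed by the forward recursion in log-space.
Decoding is max-product Viterbi with backpointers. No hard BIO transition
constraints are imposed by default: the CRF is left to learn label-order
regularities from data.

## Numerical choices

* All arithmetic is float64 on a small in-package reverse-mode autodiff
  engine (tape-based, NumPy arrays); gradients of the CRF objective flow
  into emissions, transitions and every upstream parameter.
* Impossible transitions (into START, out of STOP) are walled off with
  −1e4 rather than −inf so gradients stay finite; at sentence lengths
  ≤ 10^3 the leakage through a −1e4 wall is far below float precision.
* `logsumexp` subtracts the row maximum before exponentiation.
* Viterbi ties break toward the lowest label index (argmax convention),
  making decoding deterministic.
* The Viterbi score and a brute-force per-path sum accumulate identical
  terms in different orders and may differ by one ulp; exact comparisons
  are therefore made on paths, and on scores to 1e-9.
* Dropout uses inverted scaling with **keep**-probability 0.9 (drop rate
  0.1), applied after fusion and after attention, and is disabled at
  inference. Interpreting the 0.9 as a drop rate would remove 90 % of
  activations and prevent convergence.
* Sentences longer than `max_len − 2` are right-truncated with labels
  truncated in lockstep; at prediction time the overflow positions are
  emitted as `O` so output length always equals input length.
* An `I-t` tag whose predecessor is not `B-t`/`I-t` of the same type is
  repaired to `B-t` (CoNLL-style leniency), so every tag sequence the
  model can emit decodes to a valid mention set.

## Training configuration

Defaults (in `ModelConfig`): LSTM width 100, batch size 32, learning rate
5e-5, maximum sentence length 128, dropout keep-probability 0.9, 50
epochs, AdamW with β = (0.9, 0.999) and decoupled weight decay 0.01.
Learning-rate scheduling and gradient clipping are available but off by
default. The 5e-5 rate is appropriate when fine-tuning on top of a
pretrained encoder; the self-contained configuration (small trainable
embedding table, width 32) trains well at 1e-3, and that is the rate used
throughout the package's own benchmarks. Batches are padded tightly (to
the longest sentence in the batch, capped at `max_len`). When a dev corpus
is supplied, the returned model is the epoch checkpoint with the best dev
entity micro-F1; otherwise the final parameters are returned. All
randomness (initialization, shuffling, dropout) derives from one seed, so
metric logs are bitwise reproducible on a single platform.

## Evaluation

Entity-level scoring is strict: a predicted mention is a true positive
only when its type, start and end all match a gold mention. Precision =
TP / predicted mentions, recall = TP / gold mentions, F1 the harmonic
mean, reported per type and pooled (micro) as percentages with two
decimals; a metric with a zero denominator is 0. Strictness is a
documented choice — boundary errors (recognizing only the head of a
longer symptom phrase) must count as errors.

## Synthetic corpus generator

Real Chinese EMR benchmark corpora are access-restricted, so experiments
run on synthetic corpora that emulate their structure: short sentences
(8–18 content characters) terminated by "。", several entity types with
Poisson per-sentence mention counts, contiguous spans of 2–4 characters,
and heavily skewable type frequencies (the frequent:rare ratio in real
clinical corpora is roughly 10:1). Each type draws span characters from a
dedicated 20-character code-point block disjoint from the 60-character
background block, mimicking the clustering of medical vocabulary and
giving models a learnable signal. Spans are placed by a stars-and-bars
gap draw, so placements are uniform, non-overlapping and never cross the
terminator; mentions that cannot fit a sentence are dropped (Poisson
thinning), and rate/span combinations that would exceed 80 % of the
minimum sentence length are rejected outright. Splits are 80/10/10 by a
seeded shuffle.

What passing on this generator does **not** show: the generator has no
real clinical language — no negation, no abbreviation ambiguity, no
discontinuous or nested entities, no out-of-vocabulary characters at test
time (pools are finite and shared across splits), and type identity is
carried by character identity rather than context. Results on it
demonstrate that the architecture, objective and decoder are implemented
correctly and can exploit a clean signal, not that any particular F1 would
transfer to real EMR text.

## Benchmark problem sizes

The package's own benchmarks (test suite and `scripts/acceptance.py`) use
deliberately small, CPU-friendly conditions chosen once: 200 training
sentences for the memorization (overfit) check at 50 epochs; a
2000/250/250 split, 8 epochs and 3 seeds for the generalization check;
800 sentences, 4 epochs and 5 seeds for the two-type 10:1 imbalance
comparison; 300 random instances with n ≤ 6 and L ≤ 5 for the CRF
enumeration cross-check.

## Known limitations

* One attention stage and one BiLSTM layer; no stacked blocks, no
  positional encodings (the BiLSTM supplies position information).
* No pretrained weights ship with the package; the adapter interface
  accepts any external encoder but cannot update its parameters (a frozen
  adapter exposes embeddings only; an unfrozen one exposes gradients on
  the embedding tensor for callers that can consume them).
* The CRF offers no marginal (forward–backward posterior) output, and no
  semi-Markov or higher-order variants.
* Training is single-process CPU float64; it is sized for corpora of
  10^3–10^4 short sentences, not for full-scale benchmark reproduction.
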