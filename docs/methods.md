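# Methods

This document describes what the package computes, the choices made
where the method leaves room, and the limitations of the built-in
benchmark.

## Problem

Pool-based answer selection: each question comes with a pool of
candidate answers containing one or more correct ones, and the system
must rank the pool. Reported metrics are top-k accuracy (k = 1, 2, 3)
over pools and the precision/recall/F1 of the top-1 calls. The intended
setting is a language such as Chinese where tokenization is itself
error-prone, which motivates feeding the model both a word-level and a
character-level view of every sentence.

## Input representation

### Double-level embedding

Words and characters are embedded in the same d-dimensional space. For a
sentence with character sequence c₁…c_n and word sequence w₁…w_m, the
input matrix at position t is

    Sen_t = α · Word_t + (1 − α) · Char_t,    α ∈ [0, 1], default 0.6.

Alignment of the two views ("pad", the default): the word sequence is
zero-padded to the character length, so position t mixes the t-th word
vector (or zero beyond m) with the t-th character vector. The
alternative "broadcast" alignment repeats each word vector across its
own characters, so each character position mixes with the vector of the
word containing it; it requires a character-count map for the lexicon.
Sequences are padded with zero rows and masked, or truncated, to fixed
lengths — defaults 50 (questions) and 70 (answers) character positions,
which match the corpus averages the defaults were designed around.

Out-of-vocabulary tokens map to the zero vector by default, or to a
deterministic hash-seeded random vector (`oov_policy: hash`).

### Token embeddings

`train_token_embeddings` builds word and character tables from a corpus
with a deterministic spectral method: symmetric co-occurrence counts
within a window (default 5), positive pointwise mutual information, and
a truncated SVD to d dimensions with a sign convention fixed by the
largest-magnitude coordinate of each singular vector. The result is
reproducible bit-for-bit, independent of any seed. Pre-trained vectors
in the standard word2vec text format can be used instead.

## Encoder

### Inner attention

Before encoding, every input row is gated:

    α_t = σ(r_qᵀ M_qi x_t),    x̃_t = α_t · x_t

where r_q is the mean of the **question's** valid embedding rows and
M_qi (d × d) is trained. Answers are gated by their question's r_q —
so an answer's representation is question-conditioned — and questions by
their own r_q. Both gates can be disabled in configuration
(`attend_question`, `attend_answer`). Gating the inputs rather than the
outputs avoids the backward-position bias of post-hoc attention over RNN
states.

### Bi-LSTM and pooling

A stack of bidirectional LSTM layers (standard cell: input, forget,
output gates and tanh candidate; forget-gate bias initialized to 1,
recurrent matrices orthogonal, input matrices uniform ±0.08) processes
the gated sequence; each layer's output is the concatenation of the
forward and backward hidden states. Padded positions are masked: the
state carries through unchanged and the output row is zero, so trailing
padding never influences any result (tested). During training an
inverted-dropout mask (default rate 0.5) is applied to every layer's
output r_t — never to the recurrent connections — so evaluation needs no
rescaling. Max pooling over valid positions (mean pooling available)
produces the sentence representation.

## Similarity and objective

    Sim(q, a) = θ1 · Sim_semantic(q, a) + (1 − θ1) · Sim_text(q, a)

- **Sim_semantic** operates on the static token embeddings of the valid
  positions (word-level tokens by default; the combined double-level
  rows via `semantic_level: combined`): form the pairwise cosine matrix,
  take each row's maximum and each column's maximum, and average all
  m + n maxima. Cosine with a zero vector is defined as 0.
- **Sim_text** is the cosine of the pooled encoder representations.

Training minimizes the mean hinge loss over (q, a⁺, a⁻) triples,

    L = max(0, M − Sim(q, a⁺) + Sim(q, a⁻)),    default M = 0.1,

with Adam (default) or SGD. The semantic term contains no parameters, so
gradients flow only through Sim_text; the semantic term shifts each
triple's effective margin. Both facts are tested (a θ1 = 1 configuration
has identically zero gradient). Backpropagation is hand-written and
verified against central finite differences on every parameter group.

Triples are built per (question, correct answer) with negatives sampled
without replacement (default 5 per positive); evaluation pools contain
all of a question's correct answers plus sampled negatives up to the
pool size (default 100). Ranking ties are broken by answer id, so runs
are reproducible.

## Synthetic corpus

Words are opaque symbols composed of character symbols; the lexicon is
partitioned into disjoint topics. Each question samples its words from
one topic. Each correct answer draws a fraction `overlap_rate` of its
word tokens **from the question's own realized tokens** and the rest
from other topics. Drawing the overlap from the question's tokens rather
than from its whole topic is deliberate: with topic-level overlap,
correct answers are statistically exchangeable with same-topic
distractors, which caps every scorer's attainable top-1 well below 1 and
makes the corpus untrainable in the interesting sense; question-level
overlap keeps `overlap_rate` exact while making the correct answer
identifiable among same-topic candidates. A separate process degrades
the word-level view only: each word token is independently replaced by
its constituent characters with probability `segmentation_noise_rate`,
emulating segmentation errors while the character view stays intact.

## Design decisions

- **Learning rate** defaults to 0.01. The 0.1 setting of the original
  large-scale experiments remains available in configuration but makes
  Adam diverge at the small model sizes this package targets.
- **Dropout placement**: on every layer's output, never on recurrent
  connections. An earlier draft applied it only between stacked layers,
  which silently disabled regularization for single-layer models.
- **Attention query r_q** is the mean of the question's valid embedding
  rows — data-derived, not trained.
- **Untrained scoring mode**: without a model, the text term falls back
  to the cosine of mean token embeddings. This gives a meaningful
  baseline for "does training help" comparisons.
- **Pooling**: max pooling is the default; mean pooling is available as
  a configuration switch (`pooling: mean`) since averaging encoder
  outputs is a defensible alternative reading of feature aggregation.
- **Numerics**: cosine of a zero-norm vector is 0; all stochastic
  components (init, data order, dropout, sampling) draw from separate
  `numpy` Generator streams keyed by (seed, stage constant), so every
  pipeline stage is independently reproducible.

## Benchmark and its limitations

`qarank.benchmark.run_benchmark` fixes a desk-scale study: 10 topics,
200 training questions (2 positives each, 5 negatives per positive →
2,000 triples), 50 held-out pools of 10 candidates with one positive,
overlap 0.8, d = 16, one Bi-LSTM layer of 16 units, θ1 = 0.6, M = 0.1,
Adam 0.01, batch 50, 30 epochs. At seed 0: untrained test top-1 0.96,
trained 1.00; under segmentation noise 0.5 the double-level input scores
0.82 against 0.80 for word-only.

Limitations to keep in mind:

- **The untrained baseline is strong.** At overlap 0.8 the semantic term
  alone scores 0.96–1.00 and even an untrained (random) encoder's text
  term scores 0.72–0.90, because random Bi-LSTM features preserve
  lexical similarity. The headroom for training is therefore small: the
  initial mean hinge loss is ≈ 0.006 with only ~9 % of triples active.
- **The training gain is seed-sensitive.** Across seeds the trained
  model lands within a few pools of the untrained scorer in either
  direction; seed 0 (the default) shows a +0.04 gain. A larger, harder
  corpus (more topics, lower overlap, bigger pools) would separate the
  two more robustly but would leave desk-scale runtimes.
- **Adam drifts far on a nearly-solved objective.** With most triples
  inactive, gradients are tiny, but Adam's normalization still takes
  full-size steps; over 1,200 steps the parameters move ≈ 2.4× their
  initial norm, which can degrade the text term (SGD at the same rate
  moves ≈ 0.01× and preserves it). Dropout on the encoder output
  mitigates but does not remove this. For this benchmark the published
  optimizer (Adam) is kept; for similar small problems consider SGD or
  early stopping.
- The headline accuracies reported for the full-scale setting (60 k
  questions, 200 hidden units, 2 layers, 150 epochs, pools of 100) are
  not reproducible at this scale and are not targets of this package's
  tests.
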