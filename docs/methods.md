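# Methods

## Problem

Species-level annotation of full-length (~1500 bp) bacterial 16S rRNA gene
sequences against a curated reference database. The database poses three
difficulties at once: very high between-species sequence similarity, a
long-tailed class-frequency profile (a few species contribute hundreds of
reads, most contribute a handful, many only one), and IUPAC ambiguity
codes sprinkled through the reference sequences. The package treats the
task as supervised classification: a sequence is tokenized into
overlapping k-mers, each k-mer is mapped to a real vector by a DNA
language model, and the resulting (L−k+1) × d matrix is classified by a
convolutional network.

## Database preprocessing

Two steps run before any model sees the data.

**Ambiguity resolution.** Every ambiguity code is replaced by a base drawn
uniformly from the code's IUPAC set (N → {A,C,G,T}, R → {A,G}, …). Without
this step every k-mer touching an ambiguous base would tokenize to [UNK]
and carry no information. Resolution is a pure function of (sequence,
seed); RNG streams are keyed by record id so the output does not depend on
record order.

**Abundance-banded replication.** Species with fewer than 11 reads are
oversampled by a banded total multiplier:

| reads per species | total multiplier |
|---|---|
| 1–2 | ×12 |
| 3–5 | ×4 |
| 6–10 | ×2 |
| ≥ 11 | ×1 |

"Total multiplier" means a 2-read species ends up with 2 × 12 = 24 reads,
not 2 + 12. Each replica re-resolves its ambiguity codes independently, so
replicas of ambiguity-free sequences are exact duplicates while ambiguous
ones differ slightly. The conservation law |output| = Σ_s n_s·factor(n_s)
is enforced by test against a per-record brute-force enumeration oracle.

Replication runs **before** the train/test split by default. This inflates
train/test similarity for rare species (their test reads are near-copies
of training reads) — a known property of the procedure, visible as
unusually high TAIL accuracy in long-tail evaluation. A
`replicate_after_split`-style workflow (balance only the training part)
is available by composing the library calls in the other order.

**Stratified 90/10 split.** Per species with n reads, round(n × 0.1) test
reads clamped to [1, n−1], so every species appears in both parts. A
species with a single read is rejected with a pointer to run balancing
first (every band factor below the threshold is ≥ 2). The partition is a
pure function of the seed and is independent of record order.

## Tokenization and embedding

Sequences are normalized to uppercase DNA (U→T) at read time, then cut
into overlapping k-mers with stride 1 (L bases → L−k+1 tokens). The
vocabulary holds the five special tokens [CLS], [MASK], [PAD], [UNK],
[SEP] at fixed ids 0–4, then all 4^k DNA k-mers in lexicographic order
(69 entries at the default k = 3). Any k-mer containing a non-ACGT symbol
encodes to [UNK].

Three embedding providers share one interface (one d-dimensional row per
content token):

* **MLM embedder** — a BERT-style transformer encoder trained here with
  the masked-language-modeling objective only; there is no
  next-sentence-prediction head, as sequence classification has no paired
  sentences. Masking is BERT-convention 15% (80% → [MASK], 10% → random
  k-mer, 10% unchanged) with span masking of k contiguous tokens by
  default, because adjacent overlapping k-mers share k−1 bases and would
  otherwise leak the masked token. Spans are laid down until the target
  count is covered, then trimmed at random, so the measured masked
  fraction matches the configured rate.
* **Table embedder** — imports a token → vector TSV exported from any
  externally trained DNA language-model checkpoint, so the package does
  not depend on shipping large pretrained weights.
* **Hash embedder** — a frozen, seeded random vector per token
  (collision-free in practice). It is the desk-scale stand-in used by the
  benchmark: with stride-1 k-mers, classification signal lives in *which*
  tokens occur where, and a fixed random projection preserves that.

**Long sequences.** A 1500 bp gene yields ~1498 tokens at k = 3, beyond a
512-token encoder window. Streams are cut into overlapping windows
(default overlap 64, two slots reserved for [CLS]/[SEP]); windows are
embedded independently and stitched back with overlap rows averaged. The
round trip is exactly lossless on token ids and shape-preserving on rows.
This windowing is a design choice of this package — reasonable, simple,
and documented as such.

Embeddings are frozen during classifier training (the embedder and the
classifier are two separately trained models); fine-tuning through the
classifier is deliberately out of scope.

## Classifier

The (L′ × d) embedding matrix is treated as a single-channel 2-D feature
map, matching the use of image backbones. Two parallel branches:

* **Deep branch**: a 3×3 stride-2 stem conv + 3×3 stride-2 max-pool, then
  four stages of 2, 3, 2, 2 Split-Attention blocks (9 blocks total), with
  stride-2 downsampling entering stages 2–4, ending in global average
  pooling. Split-Attention blocks follow the ResNeSt recipe: 1×1 reduce →
  grouped 3×3 producing radix × width channels → radix branches summed,
  globally pooled, squeezed through a bottleneck 1×1 MLP → r-softmax
  weights over the radix axis (softmax per group/channel, sigmoid at
  radix 1) → weighted recombination → 1×1 expand, residual connection.
  Defaults: cardinality 1, radix 2, reduction 4.
* **Shallow branch**: three Conv3×3+ReLU layers (3/4/5 configurable for
  the depth ablation) with at most 4× total downsampling, then global
  average pooling — it preserves local detail the deep stack smooths away.

The pooled branch vectors are fused by concatenation (summation and a
gated variant exist behind config) into a linear softmax head. Baseline
variants for ablations: `cnn3` (the shallow branch alone) and `resnet34`
(stages of 3, 4, 6, 3 plain two-conv residual blocks).

Convolution hyperparameters (stem, kernels, widths, strides) are this
package's engineering defaults, stated in `DSNetaxConfig`: full-scale
stage widths [64, 128, 256, 512]; the desk-scale configuration used by the
tests and the acceptance script shrinks them to [8, 8, 16, 16] with
stem/shallow width 8. Top-k prediction breaks logit ties by ascending
label id, so rankings are deterministic.

All neural components run on a small reverse-mode autodiff engine over
numpy (`dsnetax.nn`) with im2col convolutions and fused batchnorm /
softmax-cross-entropy primitives; every primitive is verified against
central finite differences in the test suite.

## Training and evaluation

Cross-entropy, Adam (lr 1e-3), batch 32, fixed epoch budget (60 at full
scale; the desk benchmark converges within 30 and may stop early once
held-out top-1 reaches a configured ceiling). The best-held-out-top-1
weights are kept. Non-finite loss aborts immediately with diagnostics.

Evaluation reports top-k accuracy (k ∈ {1, 5}) as the fraction of test
records whose true species is among the k best-ranked predictions, plus
genus-level accuracy obtained by mapping each predicted species to its
genus. Long-tail reporting partitions the test set at cutpoints
{50, 100, 500} on **training-set** read counts: HEAD = species with
≥ c training reads, TAIL = the rest. Empty parts are flagged rather than
reported as 0%, and the size-weighted recombination of part accuracies
equals the overall accuracy exactly (a bookkeeping identity the tests
assert).

## Synthetic communities

The generator emulates the statistics that make the real task hard, with
no download:

* a 7-rank taxonomy with configurable species-per-genus;
* per-species references mutated along the taxonomy tree. The per-child
  substitution count is solved from the expected pairwise difference of
  two independently mutated sisters (p = 2q(1−q) + (2/3)q²), so the
  measured sister divergence concentrates on the configured value;
* long-tailed read counts: count(rank r) = clip(round(max·r^(−α))), with
  α defaulting to log(max/min)/log(S) so the rarest species sits at the
  minimum — with min = 1 and ≥ 8 species every replication band of the
  preprocessing table is populated;
* per-read substitutions at `within_species_rate`, then ambiguity codes
  injected at `ambiguity_rate`, always choosing a code compatible with the
  true base — so resolution is a noisy recovery process with exact
  per-code success probability 1/|code set|.

Defaults describe a realistic mock community: 1500 bp, 5% inter-species
divergence, 1% within-species substitution, 0.5% ambiguity, Zipf
abundance from 200 down to 1 read. Substitutions only (no indels) so all
reads share `seq_length`; an `indels` flag exists for robustness testing.
Everything is byte-deterministic under the seed.

**What the generator does not emulate:** sequencing error profiles,
chimeras, PCR/primer bias, conserved-vs-variable region structure within
the gene, and real phylogenetic correlation between similarity and
taxonomy. Passing the desk-scale benchmark therefore demonstrates that the
pipeline's machinery is correct and can learn highly similar classes — it
does not certify accuracy figures on a real curated database.

## Benchmark scale and numerical choices

The learning-sanity benchmark uses 20 species (2 per genus), 10% sister
divergence, 30 reads each at 400 bp, hash embeddings d = 32, and the thin
desk architecture — sized so a full training run takes minutes on one CPU
while remaining non-trivial (chance is 5%). The training-fraction
experiment repeats training at 50% and 100% of the training set over
three seeds with a 12-epoch budget and compares best held-out top-1; the
expected direction is that more data does not hurt (tolerance 3 points
for seed noise).

Numerical details: float64 throughout; BN eps 1e-5, momentum 0.1; Adam
(β₁, β₂) = (0.9, 0.999), eps 1e-8; He-style initialization with explicit
`numpy.random.Generator` seeding everywhere, so model construction,
masking, splitting and simulation are all pure functions of their seeds.
Known limitations: no GPU path, no minibatch-invariant BN statistics
(batch statistics differ between batch layouts, so bit-identical histories
require identical batch order), and training at full SILVA scale is
supported by configuration but not attempted here.
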