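# Methods

## Problem and model

`icrbp` classifies fixed-length nucleotide fragments (typically 101 nt
windows around candidate circRNA–RBP contact sites) as bound (1) or unbound
(0).  The classifier is a feed-forward pipeline:

1. **Encoding.**  Each fragment is mapped to five position-aligned feature
   matrices — KNF, a Doc2Vec-style 10-mer embedding, EIIP, CCN and ANF (see
   below) — which are concatenated channel-wise into an `L × C` input.
2. **Per-scheme reparametrization.**  Five parallel same-padded 1D
   convolutions (kernel 3, 128 filters each by default) bring the five
   blocks, whose value distributions differ widely, to a common width; the
   outputs are concatenated to 640 channels.
3. **Large-kernel conv stack.**  kernel-1 (512) → average pool 2 →
   kernel-1 (256) + batch norm → kernel-7 (256) → kernel-5 (256) + max
   pool → kernel-3 (128) + max pool → kernel-1 (128).  ReLU after every
   convolution; only pooling changes length (floor division), so a 101-nt
   input yields a 12 × 128 map.  The kernel-7/kernel-5 pair widens the
   effective receptive field relative to an all-kernel-3 stack.
4. **Hybrid attention.**  Channel attention: two per-channel descriptors —
   a global max pool, and a global average pool taken after a
   channel-preserving kernel-3 convolution over positions — pass through a
   shared two-layer bottleneck MLP (reduction 16), are summed, and pass
   through ReLU (a sigmoid gate is available as a config switch); the
   resulting weights scale each channel.  Spatial attention: per-position
   channel-wise max and mean are concatenated, a single kernel-7
   convolution reduces them to one channel, and a sigmoid gives
   per-position weights.
5. **Recurrent head.**  A bidirectional GRU (hidden 128 per direction)
   consumes the 12 positions as timesteps; its full output sequence is
   flattened, passed through dropout, and a dense softmax yields the
   class-probability pair.

Training minimizes cross-entropy with Adam (learning rate 0.003, batch 1024
auto-reduced to the data size), early-stopping on the AUC of an internal
stratified validation slice (default 10%) and restoring the best-epoch
weights.

All network code runs on a small reverse-mode autodiff core over numpy
arrays (`icrbp._autodiff`, `icrbp._layers`) written for this package:
convolutions are window-extraction plus one BLAS matmul, pooling is a
reshape-reduce, and the GRU unrolls over timesteps with gradients obtained
by backpropagation through the recorded graph.  Gradient correctness is
established in the test suite by central finite differences.

## The five encodings

With `L` the fragment length and positions indexed from 1:

* **KNF** (k = 1, 2, 3): channel k at position i is the frequency, among
  the L−k+1 k-mer slots of the fragment, of the k-mer starting at i.  The
  encoding is positional (not a single global composition vector) so that
  the per-scheme convolutions see where compositionally unusual words sit.
  Positions with no k-mer slot, and k-mers containing N, hold 0; N-bearing
  k-mers are excluded from the counts while the denominator stays L−k+1.
* **Doc2Vec-style embedding**: the corpus is tokenized into overlapping
  10-mers (stride 1); token vectors are trained with skip-gram /
  negative sampling (window 5, 5 negatives drawn from the unigram^0.75
  distribution, linearly decaying learning rate, single-threaded and
  deterministic per seed).  Position i of a fragment carries the vector of
  the 10-mer starting there; the last 9 positions and out-of-vocabulary
  tokens carry zeros.  Per-token vectors (rather than one document vector
  per fragment) keep the matrix position-aligned with the other four
  schemes.
* **EIIP**: A → 0.1260, T → 0.1335, G → 0.0806, C → 0.1340, N → 0
  (electron–ion interaction pseudopotential, a free-electron-energy proxy).
* **CCN**: (ring, chemical-function, hydrogen-bond) bits —
  A (1,1,1), C (0,1,0), G (1,0,0), T (0,0,1), N (0,0,0).
* **ANF**: d_i = (count of base s_i among positions 1..i) / i, the
  prefix-relative density; N counts as a fifth symbol.  The prefix form is
  the standard accumulated-frequency definition — a whole-sequence sum
  normalized by the prefix length |S_i| would not be a frequency — and is
  what this package implements.

U is mapped to T on ingest so every encoder operates on the DNA alphabet;
other non-ACGT symbols become N rather than being rejected, since real CLIP
fragments contain them, and every encoder defines its N behavior explicitly
(zero contribution everywhere except ANF).

## Key parameter choices

| parameter | default | note |
|---|---|---|
| fragment length | 101 nt | CLIP-fragment convention; shorter inputs are N-padded symmetrically, longer ones center-cropped |
| KNF k values | 1, 2, 3 | mono/di/tri-nucleotide composition |
| embedding dim / window / epochs | 100 / 5 / 20 | `EncodingConfig.small()` uses dim 16, 5 epochs for CPU-scale runs |
| embedding min_count | 5 | word2vec convention; see below |
| conv widths | 128 per scheme; 512/256/128 stack | `ModelConfig.small()` scales to 16; 64/32/16 with GRU hidden 32 |
| attention reduction | 16 | bottleneck ratio of the channel MLP |
| GRU hidden / dropout | 128 / 0.8 | dropout read as drop probability and applied to the flattened head only; `small()` uses 0.25 |
| learning rate / batch | 0.003 / 1024 | batch auto-reduced to the dataset size |

**min_count = 5.**  Tokens seen fewer than five times in the training
corpus get no vector.  This matters more than it may appear: in i.i.d.
random backgrounds nearly every 10-mer is unique to one training sequence,
and with `min_count=1` those hapax vectors act as sequence-identity
features — the model memorizes training fragments through them, validation
AUC (whose fragments share the embedding corpus) looks excellent, and
held-out AUC collapses.  Filtering hapax tokens (the word2vec default
behavior) removes the leak; recurring tokens — in particular those spanning
a shared motif — keep their vectors.

**Channel-attention activation.**  ReLU is the default gate, with sigmoid
(the original CBAM gate, which bounds the output by the input elementwise)
as a config switch.  **Dropout 0.8** is interpreted as the drop
probability; it is a config field because the keep-probability reading is
also defensible.  **Depth variants** add or remove two kernel-1 layers: the
removal drops the first and last kernel-1 convolutions; the addition
inserts two kernel-1 (256) layers after the batch-norm stage.

## Synthetic benchmark

The generator emulates the structure of CLIP-derived benchmarks: balanced
classes of fixed-length fragments where positives differ from negatives by
a short sequence signal.  Defaults — the study conditions used by the test
suite — are 500 fragments per class, length 101, uniform base composition,
and the non-degenerate 8-mer `TGACGTCA` written into 90% of positives at a
uniform position (degenerate IUPAC motifs are supported; codes realize
uniformly over their letters).  Negatives are pure background and are not
screened for chance motif hits, mirroring how real negative fragments are
drawn; under these defaults the chance-hit rate is (101−8+1)/4^8 ≈ 0.14%.

What passing on this generator does **not** show: real binding sites have
positional and structural biases, non-uniform background composition,
shared subsequences between classes and label noise; none of these are
modelled.  The generator establishes that the pipeline can learn a planted
signal end-to-end and that its pieces compose correctly, not that the
architecture ranking on real CLIP data is reproduced.  In particular, the
block-ablated variants (e.g. BiGRU directly on the per-scheme convolution
output) solve the planted-motif task about as well as the full model —
differences between them on this benchmark are within seed-to-seed noise
(±0.02 AUC), so contribution analyses of the blocks are meaningful only on
data where long-range structure and feature interactions carry signal.

On this benchmark, the width-reduced model (`ModelConfig.small()`,
`EncodingConfig.small()`, batch 64, learning rate 0.001, ≤30 epochs,
patience 8 on a 15% validation slice) reaches held-out AUC well above 0.9
in a few minutes on one CPU.  The learning rate follows the usual
batch-size scaling: the default 0.003 is paired with batch 1024, and at
batch 64 that step size makes the deep stack oscillate without converging.  The test suite and examples use these reduced sizes throughout;
the full-width architecture is exercised for shape and gradient contracts
rather than trained to convergence.

## Numerical and design notes

* All "k×k" kernel sizes are realized as 1D kernels of size k over the
  position axis (the input is a length × channels sequence); "2×2 average
  pooling, stride 2" is pool size 2, stride 2.
* Convolutions are same-padded; pooling floor-divides; an input must
  survive the three halvings (length ≥ 8) or model assembly fails with the
  required minimum.
* AUC is computed as the rank statistic (midrank tie handling), equivalent
  to the trapezoidal area under the ROC curve; the test suite checks it
  against an explicit pairwise-comparison oracle.
* Metrics with zero denominators (e.g. FPR on an all-positive fold) are
  reported as 0 and flagged in `MetricReport.undefined` instead of raising,
  so small-fold sweeps complete.
* Ties in max pooling send the gradient to the first maximizer.
* ReLU convolutions use He (variance-preserving) initialization; batch norm
  sits between the convolution and its ReLU.
* The channel-attention MLP's output bias starts at 0.5 so the ReLU gate is
  open at initialization — with a zero bias an early all-negative MLP
  output zeroes every channel and permanently kills the gradient.
* Cross-validation retrains the k-mer embedding per fold on that fold's
  training portion only, avoiding token-statistics leakage into the
  validation fold.
* The BiGRU head flattens the full output sequence (not just the final
  hidden state) ahead of the dense layer.
* A printed reference encoding of `GTACCGA` under CCN disagrees with the
  stated per-base rule table at the T position; the rule table is
  authoritative here and is what the implementation and tests follow.

## Known limitations

* CPU-bound: the numpy network trains the width-reduced configuration
  comfortably but the full-width model at realistic corpus sizes calls for
  a GPU framework.
* The embedding ignores document identity; fragments contribute only
  token-context pairs.
* No secondary-structure features and no handling of back-splice junctions;
  inputs are plain fragments.
* Early stopping on a small validation slice is noisy; reported AUCs on
  small synthetic runs vary by a few points across seeds.
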