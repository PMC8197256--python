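# Methods

## Overview

`kmerbind` predicts whether a fixed-length DNA fragment is bound by a
transcription factor (TF). The method has three stages:

1. **Combined-sequence construction.** Each fragment (default 200 bp) is
   expanded into the concatenation of its four strand readings — original,
   complement, inverse (plain reversal), and inverse complement — giving an
   800 bp combined sequence. A TF can bind either strand in either
   orientation; the combined input presents all four readings to the
   classifier at once. "Inverse" is interpreted as string reversal, so
   "complementary inverse" coincides with the usual reverse complement.
   The concatenation order is configurable and recorded on every
   `CombinedSequence` (default: original, complement, inverse,
   inverse complement). Tokenization slides across the whole combined
   string as one sentence, so k-mers may straddle variant junctions; this
   is what makes an 800 bp input produce exactly 798 tokens at k=3, s=1
   rather than 4 x 198.

2. **k-mer embedding.** The combined sequence is segmented into
   overlapping k-mers (window k, stride s; defaults k=3, s=1, giving
   floor((l-k)/s)+1 tokens). Treating sequences as sentences and k-mers
   as words, a continuous-bag-of-words (CBOW) word2vec model with negative
   sampling learns a d=100-dimensional vector per k-mer; a sequence then
   becomes an (n_tokens x 100) real matrix (798 x 100 under the defaults).
   A one-hot-of-k-mers featurizer (n_tokens x 4^k) is the baseline
   representation.

3. **CNN + bi-LSTM classifier.** Three convolution modules (1-D conv,
   ReLU, batch normalization, max-pool) extract and downsample local motif
   features; a bidirectional LSTM captures longer-range structure; two
   fully-connected layers with one dropout layer and a sigmoid output
   produce the binding probability. Ablation variants drop the recurrent
   module (`cnn_only`) or the convolutional stack (`rnn_only`).

The neural network and the CBOW trainer are implemented directly in numpy
(forward and backward passes, including full backpropagation through time
in the LSTM, and Adam/AdaDelta optimizers). Gradient correctness is
checked in the test suite against central-difference directional
derivatives and, for the LSTM cell, against a scalar-loop reference.

## Dataset construction

Positives are fixed-width windows centered on the summits (or midpoints)
of the highest-scoring ChIP-seq peaks. Negatives are matched to the
positives on length and GC content — otherwise the classes separate on
composition alone — at negative:positive ratios 1, 2, or 3. Each negative
has a designated positive partner; two samplers are available:

* `shuffle` (default): mononucleotide shuffle of the partner (exact GC and
  length match; repeat structure destroyed);
* `background`: rejection sampling from a background pool or generator
  until the candidate's GC is within `gc_tolerance` (default 0.02) of the
  partner's, with up to 1,000 attempts, one tolerance doubling, and an
  error if matching still fails. Repeat-fraction matching is only
  approximated by this sampler, via whatever repeat content the supplied
  background carries.

A negative identical to any positive is resampled. Evaluation uses
stratified 3-fold cross-validation; within each training portion, 1/8 of
the records (floor) form a validation set used solely for model selection.

## Training protocol

Binary cross-entropy minimized by Adam, batch size 64, 20 epochs.
After every epoch the validation ROC AUC is recorded; the returned
parameters are those of the best validation epoch, not the last. Weights
are Xavier-uniform initialized, biases zero. Hyperparameter defaults
(3 conv modules, 16 channels, kernel 3, pool 2, 16 LSTM units per
direction, dropout 0.1 between the fully-connected layers, learning rate
1e-3) are the recommended starting points; they sit inside a documented
search space (kernel in {3, 9, 16, 24}, learning rate in {1e-2..1e-5},
dropout in {0.1, 0.2, 0.5}, ...), and the protocol tunes within that
space by validation ROC AUC per dataset. F1 is reported at a fixed 0.5
threshold (recorded in every `MetricsReport`).

Embeddings are retrained on each fold's training+validation sequences
only, so no held-out information leaks into the representation (a flag
restores whole-corpus training). Out-of-vocabulary tokens at predict time
map to the zero vector — deterministic, shape-preserving, and neutral for
the downstream convolution.

## The bi-LSTM head: a design note

How the recurrent module feeds the fully-connected head is genuinely
open. Two standard wirings exist: concatenating the final hidden state of
each direction (2H features), or passing the full output sequence (every
h_t, both directions, flattened). We ship both
(`ModelConfig.lstm_output`), with the full sequence as the default, for a
concrete reason: at initialization every gate sits near sigma(0) = 0.5,
so cell memory decays roughly 2^-d with distance d from the sequence end.
With ~98 pooled steps, a motif implanted uniformly in the fragment is
numerically invisible to the final hidden states for most positions, and
at small sample sizes the network memorizes instead of learning
(held-out AUC ~0.5). Feeding the whole output sequence makes every
position's features directly visible to the head and fixes this; it is
also the wiring used by the well-known hybrid CNN/bi-LSTM genomics
models that this architecture follows.

## CBOW trainer: numerical choices

Mini-batched negative-sampling updates: per batch, per-row gradients are
accumulated through a sparse (vocab x batch) matrix product and applied
once, averaged over each row's number of occurrences in the batch.
Averaging keeps the effective step size independent of batch size and
token frequency — essential for DNA k-mer corpora, where a k=3 vocabulary
has only 64 words, each extremely frequent; naively summed updates
diverge. The learning rate (default 0.3, decayed linearly to 0.01)
is calibrated for these averaged steps rather than word2vec's
per-example schedule. Frequent-word subsampling is available
(`CbowConfig.subsample`) but defaults off: with uniform k-mer
frequencies near 1/64 it would discard most of the corpus uniformly at
the usual 1e-3 setting. Remaining defaults — window 5,
10 epochs, min_count 1, 5 negative samples (unigram^0.75 noise) — are
conventional. All are recorded in `EmbeddingModel.meta`; a fixed seed
reproduces vectors bit-for-bit.

One property worth knowing: on a motif-free i.i.d. background corpus,
all 64 3-mers have nearly identical context distributions, and trained
vectors share a dominant common direction (pairwise cosine ~0.999); the
discriminative structure lives in a small residual. This is faithful CBOW
behaviour on such a corpus, not an artifact — batch normalization in the
first convolution module removes the common component downstream. Real
genomic corpora have far more k-mer context structure.

## Synthetic data generator

The generator emulates the statistical structure of ChIP-seq-derived
training sets: positives are i.i.d. background sequences (P(G)=P(C)=gc/2,
default gc 0.5) with one motif instance sampled column-wise from a PWM
and implanted at a uniform (or center-biased, binomial) random offset —
on the forward or reverse-complement strand with probability 0.5 each.
Negatives are fresh background draws GC-matched to a positive partner via
the rejection sampler (tolerance 0.02); they share the background law
rather than being shuffled positives, so no implant remnants leak into
the negative class. A ground-truth table records every implant position
and strand.

The bundled default motif is a 12-column PWM with consensus probability
0.85 per column (consensus TGACGTCATGCA): strong enough to be learnable
at moderate sample sizes, weak enough that representation choices remain
non-degenerate. Against an oracle PWM log-odds scan (the ideal detector),
the default dataset at n_pos=500, ratio 1, 200 bp has a ROC AUC ceiling
of about 0.95 — the implant occupies 12 of 200 bp, and background can
occasionally imitate it.

What the generator does **not** emulate: genomic repeat structure,
multi-occurrence or cooperative motifs, chromatin context, peak-calling
noise, and the k-mer context heterogeneity of real genomes. Passing
tests on this material demonstrates that the pipeline's machinery works
and that the model can learn planted sequence signals; it does not
certify performance on real ChIP-seq data.

## Benchmark problem sizes

The end-to-end benchmark trains on 1,000 records (500 positives, ratio
1:1, 200 bp) with one stratified third held out as the test set and 1/8
of the remainder as validation; the label-shuffled control reuses the
same features with permuted labels. These sizes keep a full run —
embedding training included — in the minutes range on a single CPU while
leaving the task non-trivial (about 200 optimizer steps per fit). Unit
and property tests use 30-60 bp fragments and tiny embedding
configurations.

## Degenerate inputs and tie-breaking

* Sequences shorter than k raise an explicit empty-sentence error.
* An all-N sequence has undefined GC content (error).
* Peak ranking ties break by (chromosome, start) for determinism.
* Max-pooling uses non-overlapping windows (stride = window), dropping a
  trailing remainder shorter than the window; ties within a pool window
  resolve to the first maximum.
* ROC AUC counts tied scores as 1/2; F1 is 0 when nothing is predicted
  positive; both error on single-class inputs rather than guessing.
* A checkpoint refuses to load under a mismatched architecture config
  (config hash check).

## Known limitations

* **Small-sample motif learning.** At the bundled benchmark scale
  (500 positives, 1:1 negatives, batch 64, 20 epochs) a fit sees only
  about 200 optimizer steps. The acceptance script reports both the
  model's held-out ROC AUC and the PWM-scan oracle ceiling on the same
  data; at this scale the model does not reach the ceiling — its
  accuracy is limited by the optimizer-step budget, not by the task,
  and grows steadily with dataset size. The architecture's local
  max-pooling plus dense head lacks the global-pooling inductive bias
  that makes motif detection easy at small n; at the data volumes the
  training protocol was designed for (tens of thousands of fragments,
  thousands of optimizer steps) this does not bind.
* The numpy network trains on CPU only and is not optimized for large
  corpora; the regime of ~15,000 positives per dataset is out of
  desk-scale reach here.
* Variable-length input is unsupported by design (fixed-width windows).
* dna2vec-style aggregation over variable k is not implemented; the
  embedding is fixed-k CBOW trained on the task corpus.
* `rnn_only` on full-length token sequences is expensive; the ablation
  runner can subsample the token axis for that variant
  (`FeatureConfig.rnn_subsample`), which is recorded in its output.
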