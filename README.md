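# kmerbind

Transcription factors (TFs) bind short degenerate DNA patterns (motifs);
locating their binding sites from sequence alone is a central problem in
regulatory genomics. `kmerbind` implements a hybrid deep-learning
pipeline for predicting TF binding from fixed-length DNA fragments, built
for researchers who want an end-to-end, dependency-light, fully
reproducible implementation they can train and probe on a single CPU.

## Method

Given a fragment s of length l (default 200 bp):

1. **Combined sequence.** Concatenate s, its complement, its inverse
   (reversal), and its inverse complement into one 4l sequence (800 bp),
   so a motif on either strand, in either orientation, appears in the
   input.
2. **k-mer sentence.** Slide a window of size k with stride s across the
   combined sequence: floor((l'-k)/s) + 1 tokens (798 for l'=800, k=3,
   s=1). The sequence AGCCT at k=3, s=1 reads (AGC, GCC, CCT).
3. **Embedding.** Train CBOW word2vec vectors (d=100, negative sampling)
   on the k-mer corpus; each fragment becomes a 798 x 100 matrix. A
   one-hot-of-k-mers featurizer (798 x 4^k) is the baseline.
4. **Classifier.** Three convolution modules (1-D conv -> ReLU -> batch
   norm -> max-pool), a bidirectional LSTM with the standard gate
   equations

       f_t = sigma(W_f x_t + U_f h_{t-1} + b_f)
       i_t = sigma(W_i x_t + U_i h_{t-1} + b_i)
       c_t = f_t . c_{t-1} + i_t . tanh(W_c x_t + U_c h_{t-1} + b_c)
       o_t = sigma(W_o x_t + U_o h_{t-1} + b_o)
       h_t = o_t . tanh(c_t)

   and a two-layer fully-connected head with dropout and a sigmoid
   output: P(bound) = f_pred(f_rnn(f_cnn(x))).

Training minimizes binary cross-entropy with Adam (batch 64, lr 1e-3,
20 epochs); the model with the best validation ROC AUC is kept.
Evaluation uses stratified 3-fold cross-validation (1/8 of each training
portion held out for validation) and reports ROC AUC, PR AUC, and F1.
The network and the CBOW trainer are implemented in numpy, including all
backward passes; see `docs/methods.md` for the design notes.

Datasets are built from ranked peak files (narrowPeak/BED + genome FASTA:
fixed-width windows around the top-N summits) or from the bundled
synthetic generator, which implants a position-weight-matrix motif into
background sequences and GC-matches the negatives — so the whole pipeline
is testable without any external downloads.

## Worked example

```python
from kmerbind import (DNASequence, build_combined, tokenize,
                      build_corpus, train_cbow, embed)
from kmerbind.simulate import SimConfig, generate_dataset

seq = DNASequence("demo", "AGCCT")
print(tokenize(seq, k=3).tokens)          # ('AGC', 'GCC', 'CCT')

dataset, truth = generate_dataset(SimConfig(n_pos=50, seq_length=200, seed=7))
corpus = build_corpus(dataset.sequences, k=3, stride=1, combined=True)
model = train_cbow(corpus)
matrix = embed(corpus[0], model)
print(len(build_combined(dataset.sequences[0])))   # 800
print(matrix.values.shape)                          # (798, 100)
```

The combined 200 bp fragment is 800 bp long; its 798 3-mers embed into a
798 x 100 matrix — the classifier's input.

The same flow from the shell:

```sh
kmerbind simulate --n-pos 500 --ratio 1 --seed 1 --out runs/sim
kmerbind train --pos-fasta runs/sim/sim_pos.fa --neg-fasta runs/sim/sim_neg.fa \
               --seed 1 --out runs/model
kmerbind predict --model-dir runs/model --fasta runs/sim/sim_pos.fa \
               --out runs/preds.tsv
```

`train` prints the best validation ROC AUC and the held-out metrics;
`predict` writes per-sequence binding probabilities in (0, 1).

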