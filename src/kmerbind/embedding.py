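"""Distributed k-mer representations: CBOW training and featurization.

Treating each sequence as a sentence and each k-mer as a word, a
continuous-bag-of-words (CBOW) model with negative sampling learns a dense
d-dimensional vector per k-mer from its flanking context. A tokenized
sequence then becomes an (n_tokens x d) real matrix — for a 200 bp input
combined to 800 bp and tokenized at k=3, s=1, a 798 x 100 matrix.

The trainer is written directly in numpy. Updates are mini-batched:
gradients of all (target, context, negatives) examples in a batch are
summed via sparse accumulation and applied once, which makes training fast
and, with a fixed seed, exactly reproducible. Frequent-word subsampling
(as in standard word2vec) is available but off by default: with a k=3
vocabulary of 64 words all tokens are frequent, and the usual 1e-3
setting would discard most of the corpus uniformly.

A one-hot-of-k-mers featurizer is provided as the baseline representation
(n_tokens x 4^k, one 1 per row at the token's lexicographic index).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.sparse as sp

from .seqrep import (
    DNASequence,
    KmerSentence,
    build_combined,
    tokenize,
    DEFAULT_VARIANT_ORDER,
)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class CbowConfig:
    """Hyperparameters of the CBOW trainer.

    d=100 is the embedding dimension used throughout the pipeline; the
    remaining values are conventional word2vec settings.
    """

    d: int = 100
    window: int = 5
    epochs: int = 10
    min_count: int = 1
    negative: int = 5
    learning_rate: float = 0.3
    min_learning_rate: float = 0.01
    subsample: float = 0.0
    batch_size: int = 4096
    seed: int = 0


@dataclass
class EmbeddingModel:
    """Vocabulary of k-mer tokens mapped to fixed-dimension real vectors."""

    vocab: dict[str, int]
    vectors: np.ndarray  # (|vocab|, d)
    k: int
    stride: int
    meta: dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return int(self.vectors.shape[1])

    def vector(self, token: str) -> np.ndarray:
        """Vector for ``token``; zero vector if out-of-vocabulary."""
        idx = self.vocab.get(token)
        if idx is None:
            return np.zeros(self.d, dtype=self.vectors.dtype)
        return self.vectors[idx]


@dataclass(frozen=True)
class SequenceMatrix:
    """Dense featurization of one sentence: (n_tokens x d) real matrix."""

    values: np.ndarray
    source_id: str
    featurizer: Literal["cbow", "onehot"]


# ---------------------------------------------------------------------------
# corpus construction
# ---------------------------------------------------------------------------

def build_corpus(
    sequences: Sequence[DNASequence],
    k: int,
    stride: int = 1,
    combined: bool = True,
    order: Sequence[str] = DEFAULT_VARIANT_ORDER,
) -> list[KmerSentence]:
    """Tokenize every sequence into one sentence, optionally combining strands.

    With ``combined=True`` each sequence is first expanded to its
    four-strand concatenation, and the k-mer window slides across the whole
    concatenated string as one sentence (tokens may straddle variant
    junctions).
    """
    if len(sequences) == 0:
        raise ValueError("cannot build a corpus from an empty sequence list")
    sentences = []
    for seq in sequences:
        source = build_combined(seq, order) if combined else seq
        sentences.append(tokenize(source, k=k, stride=stride, source_id=seq.id))
    return sentences


# ---------------------------------------------------------------------------
# CBOW training
# ---------------------------------------------------------------------------

def _build_vocab(sentences: Sequence[KmerSentence], min_count: int) -> tuple[dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(tok for tok, c in counts.items() if c >= min_count)
    vocab = {tok: i for i, tok in enumerate(kept)}
    freqs = np.array([counts[tok] for tok in kept], dtype=np.float64)
    return vocab, freqs


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_cbow(
    corpus: Sequence[KmerSentence],
    config: CbowConfig | None = None,
    **overrides,
) -> EmbeddingModel:
    """Train CBOW-with-negative-sampling k-mer vectors on a tokenized corpus.

    For each surviving target token, the mean of the input vectors of its
    window context predicts the target against ``negative`` sampled
    decoys (unigram^0.75 noise distribution); logistic loss gradients
    update both vector tables. Two runs with the same config and seed
    produce identical vectors.

    A corpus whose sentences are all shorter than two tokens has no
    (context, target) pairs; a warning-level degenerate model is still
    returned with its randomly initialized vectors.
    """
    if config is None:
        config = CbowConfig()
    if overrides:
        config = CbowConfig(**{**config.__dict__, **overrides})
    if len(corpus) == 0:
        raise ValueError("cannot train CBOW on an empty corpus")
    ks = {s.k for s in corpus}
    ss = {s.stride for s in corpus}
    if len(ks) != 1 or len(ss) != 1:
        raise ValueError(f"corpus mixes (k, stride) provenance: k={ks}, stride={ss}")
    k, stride = ks.pop(), ss.pop()

    vocab, freqs = _build_vocab(corpus, config.min_count)
    V, d = len(vocab), config.d
    rng = np.random.default_rng(config.seed)
    w_in = rng.uniform(-0.5 / d, 0.5 / d, size=(V, d)).astype(np.float32)
    w_out = np.zeros((V, d), dtype=np.float32)

    # sentences as id arrays; tokens below min_count are dropped from training
    sent_ids = [
        np.array([vocab[t] for t in s.tokens if t in vocab], dtype=np.int64)
        for s in corpus
    ]
    sent_ids = [a for a in sent_ids if a.size >= 2]

    meta = {
        "window": config.window,
        "epochs": config.epochs,
        "seed": config.seed,
        "min_count": config.min_count,
        "negative": config.negative,
        "subsample": config.subsample,
        "algorithm": "cbow-negative-sampling",
    }
    if not sent_ids:
        import warnings

        warnings.warn(
            "corpus has no sentence with >= 2 in-vocabulary tokens; "
            "returning a degenerate (untrained) embedding model"
        )
        meta["degenerate"] = True
        return EmbeddingModel(vocab=vocab, vectors=w_in, k=k, stride=stride, meta=meta)

    total = freqs.sum()
    # frequent-word subsampling keep-probability (word2vec convention)
    if config.subsample > 0:
        f = freqs / total
        keep = np.minimum(1.0, np.sqrt(config.subsample / f) + config.subsample / f)
    else:
        keep = np.ones(V)
    noise = (freqs ** 0.75) / (freqs ** 0.75).sum()

    w = config.window
    offs = np.concatenate([np.arange(-w, 0), np.arange(1, w + 1)])
    all_ids = np.concatenate(sent_ids)
    sent_of = np.repeat(np.arange(len(sent_ids)),
                        [a.size for a in sent_ids])
    noise_cdf = np.cumsum(noise)
    n_steps_total = max(config.epochs, 1)
    for epoch in range(config.epochs):
        lr = config.learning_rate + (config.min_learning_rate - config.learning_rate) * (
            epoch / n_steps_total
        )
        # Materialize this epoch's training examples across the whole
        # corpus at once: subsample tokens, then take as context the
        # surviving tokens within `window` positions on either side,
        # masked at sentence boundaries.
        if config.subsample > 0:
            sub = rng.random(all_ids.size) < keep[all_ids]
            ids, sid = all_ids[sub], sent_of[sub]
        else:
            ids, sid = all_ids, sent_of
        n = ids.size
        if n < 2:
            continue
        pos = np.arange(n)[:, None] + offs[None, :]  # (n, 2w)
        pos_c = np.clip(pos, 0, n - 1)
        valid = (pos >= 0) & (pos < n) & (sid[pos_c] == sid[:, None])
        targets = ids
        contexts = np.where(valid, ids[pos_c], -1)  # -1 = pad
        perm = rng.permutation(n)
        targets, contexts = targets[perm], contexts[perm]

        negs = np.searchsorted(noise_cdf, rng.random((n, config.negative)))

        B = config.batch_size
        for start in range(0, targets.size, B):
            t = targets[start : start + B]
            ctx = contexts[start : start + B]
            neg = negs[start : start + B]
            b = t.size
            mask = ctx >= 0  # (b, 2w)
            n_ctx = np.maximum(mask.sum(axis=1), 1)
            ctx_safe = np.where(mask, ctx, 0)

            # sparse (V, b) accumulator for the context side; its transpose
            # also computes the context-mean hidden vector h without
            # materializing a (b, 2w, d) gather
            w_ctx = ctx.shape[1]
            cols_ctx = np.repeat(np.arange(b), w_ctx)
            cdata = (mask / n_ctx[:, None]).astype(np.float32).ravel()
            cacc = sp.csr_matrix(
                (cdata, (ctx_safe.ravel(), cols_ctx)), shape=(V, b)
            )
            h = cacc.T @ w_in  # (b, d) mean of context vectors

            out_ids = np.concatenate([t[:, None], neg], axis=1)  # (b, 1+neg)
            labels = np.zeros_like(out_ids, dtype=np.float32)
            labels[:, 0] = 1.0
            u = w_out[out_ids]  # (b, 1+neg, d)
            scores = _sigmoid(np.einsum("bd,bnd->bn", h, u).astype(np.float32))
            g = scores - labels  # (b, 1+neg)

            gh = np.einsum("bn,bnd->bd", g, u)  # gradient wrt h

            # Sparse accumulation: per-row gradients summed via a sparse
            # (V, b) matrix product, then averaged over each row's number of
            # occurrences in the batch. Averaging keeps the step size
            # independent of batch size and token frequency — essential
            # here, where a k=3 vocabulary has only 64 very frequent words
            # and summed updates would diverge.
            n_out = out_ids.shape[1]
            cols_out = np.repeat(np.arange(b), n_out)
            acc = sp.csr_matrix(
                (g.ravel(), (out_ids.ravel(), cols_out)), shape=(V, b)
            )
            occ_out = np.bincount(out_ids.ravel(), minlength=V).astype(np.float32)
            scale_out = lr / np.maximum(occ_out, 1.0)
            w_out -= scale_out[:, None] * (acc @ h)

            occ_in = np.bincount(ctx_safe.ravel(), weights=mask.ravel(),
                                 minlength=V).astype(np.float32)
            scale_in = lr / np.maximum(occ_in, 1.0)
            w_in -= scale_in[:, None] * (cacc @ gh)

    return EmbeddingModel(vocab=vocab, vectors=w_in, k=k, stride=stride, meta=meta)


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def embed(sentence: KmerSentence, model: EmbeddingModel) -> SequenceMatrix:
    """Look up each token's vector; out-of-vocabulary tokens map to zero.

    Raises if the sentence's k differs from the model's k.
    """
    if sentence.k != model.k:
        raise ValueError(
            f"sentence k={sentence.k} does not match embedding model k={model.k}"
        )
    mat = np.zeros((len(sentence.tokens), model.d), dtype=model.vectors.dtype)
    for i, tok in enumerate(sentence.tokens):
        idx = model.vocab.get(tok)
        if idx is not None:
            mat[i] = model.vectors[idx]
    return SequenceMatrix(values=mat, source_id=sentence.source_id, featurizer="cbow")


def kmer_index(token: str) -> int:
    """Lexicographic index of an {A,C,G,T} k-mer (A=0 ... T=3, base-4)."""
    idx = 0
    for ch in token:
        if ch not in _BASE_INDEX:
            raise ValueError(f"token {token!r} contains non-ACGT character {ch!r}")
        idx = idx * 4 + _BASE_INDEX[ch]
    return idx


def index_kmer(idx: int, k: int) -> str:
    bases = []
    for _ in range(k):
        bases.append("ACGT"[idx % 4])
        idx //= 4
    return "".join(reversed(bases))


def one_hot_kmers(
    sentence: KmerSentence, n_policy: Literal["strict", "drop"] = "strict"
) -> SequenceMatrix:
    """One-hot encode a sentence over the 4^k k-mer alphabet.

    Each row has exactly one 1, at the token's lexicographic index.
    Tokens containing N either raise (``strict``, default) or are dropped
    (``drop``; the row count then falls below the sentence length).
    """
    k = sentence.k
    rows = []
    for tok in sentence.tokens:
        if "N" in tok:
            if n_policy == "strict":
                raise ValueError(
                    f"token {tok!r} contains N; one-hot encoding is defined over ACGT only"
                )
            continue
        rows.append(kmer_index(tok))
    mat = np.zeros((len(rows), 4**k), dtype=np.float32)
    mat[np.arange(len(rows)), rows] = 1.0
    return SequenceMatrix(values=mat, source_id=sentence.source_id, featurizer="onehot")


def decode_one_hot(matrix: SequenceMatrix, k: int) -> tuple[str, ...]:
    """Invert :func:`one_hot_kmers` via per-row argmax."""
    return tuple(index_kmer(int(i), k) for i in matrix.values.argmax(axis=1))


# ---------------------------------------------------------------------------
# word2vec text-format I/O
# ---------------------------------------------------------------------------

def save_word2vec(model: EmbeddingModel, path: str | Path) -> None:
    """Write vectors in word2vec text format: header 'V d', then one token per line."""
    with open(path, "w") as fh:
        fh.write(f"{len(model.vocab)} {model.d}\n")
        inv = sorted(model.vocab, key=model.vocab.get)
        for tok in inv:
            vec = " ".join(repr(float(x)) for x in model.vectors[model.vocab[tok]])
            fh.write(f"{tok} {vec}\n")


def load_word2vec(path: str | Path, k: int, stride: int = 1) -> EmbeddingModel:
    with open(path) as fh:
        header = fh.readline().split()
        V, d = int(header[0]), int(header[1])
        vocab: dict[str, int] = {}
        vectors = np.zeros((V, d), dtype=np.float32)
        for i, line in enumerate(fh):
            parts = line.split()
            vocab[parts[0]] = i
            vectors[i] = np.array(parts[1:], dtype=np.float32)
    if len(vocab) != V:
        raise ValueError(f"header promises {V} vectors, file has {len(vocab)}")
    return EmbeddingModel(vocab=vocab, vectors=vectors, k=k, stride=stride,
                          meta={"loaded_from": str(path)})
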