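"""Strand-variant construction and k-mer tokenization.

A double-stranded DNA fragment can be read four ways: the original strand,
its complement, its reversal ("inverse"), and the reverse complement.
Concatenating all four into one *combined sequence* exposes the classifier
to every reading of the fragment, so a motif landing on either strand (in
either orientation) appears somewhere in the input. A 200 bp fragment
yields an 800 bp combined sequence.

Sequences are then segmented into overlapping k-mers ("words") with a
sliding window of size ``k`` and stride ``s``; the ordered token list is a
*sentence* for the downstream word-embedding model. With k=3 and s=1 an
800 bp combined sequence yields 798 tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: canonical tags for the four strand variants, in the default concatenation order
DEFAULT_VARIANT_ORDER = ("original", "complement", "inverse", "inverse_complement")


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class EmptySentenceError(ValueError):
    """Tokenization was requested on a sequence shorter than k."""


class VariantOrderError(ValueError):
    """A combined-sequence variant order is not a permutation of the four tags."""


@dataclass(frozen=True)
class DNASequence:
    """A validated DNA sequence over {A, C, G, T, N}.

    Lowercase input is normalized to uppercase on construction; any other
    character raises :class:`InvalidSequenceError` naming its position.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        if not bases:
            raise InvalidSequenceError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(bases):
            if ch not in ALPHABET:
                raise InvalidSequenceError(
                    f"sequence {self.id!r} has invalid character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class CombinedSequence:
    """Concatenation of the four strand variants of one source sequence."""

    source_id: str
    bases: str
    order: tuple[str, ...] = DEFAULT_VARIANT_ORDER

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class KmerSentence:
    """Ordered k-mer tokens of one sequence, with (k, stride) provenance."""

    tokens: tuple[str, ...]
    k: int
    stride: int
    source_id: str

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)


# ---------------------------------------------------------------------------
# strand variants
# ---------------------------------------------------------------------------

def complement(seq: DNASequence) -> DNASequence:
    """Watson-Crick complement (A<->T, C<->G, N->N), preserving order."""
    return DNASequence(seq.id, seq.bases.translate(_COMPLEMENT))


def inverse(seq: DNASequence) -> DNASequence:
    """Plain string reversal of the sequence; base composition unchanged."""
    return DNASequence(seq.id, seq.bases[::-1])


def inverse_complement(seq: DNASequence) -> DNASequence:
    """Reverse complement: ``inverse(complement(seq))``."""
    return DNASequence(seq.id, seq.bases.translate(_COMPLEMENT)[::-1])


_VARIANT_FUNCS = {
    "original": lambda s: s,
    "complement": complement,
    "inverse": inverse,
    "inverse_complement": inverse_complement,
}


def build_combined(
    seq: DNASequence, order: Sequence[str] = DEFAULT_VARIANT_ORDER
) -> CombinedSequence:
    """Concatenate the four strand variants of ``seq`` in ``order``.

    The result has length 4*len(seq). ``order`` must be a permutation of
    the four variant tags; the order used is recorded on the result so an
    experiment's input construction is reproducible.
    """
    order = tuple(order)
    if sorted(order) != sorted(_VARIANT_FUNCS):
        raise VariantOrderError(
            f"variant order must be a permutation of {sorted(_VARIANT_FUNCS)}, got {order}"
        )
    parts = [_VARIANT_FUNCS[tag](seq).bases for tag in order]
    return CombinedSequence(source_id=seq.id, bases="".join(parts), order=order)


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

def tokenize(bases: str | DNASequence | CombinedSequence, k: int, stride: int = 1,
             source_id: str | None = None) -> KmerSentence:
    """Segment a sequence into k-mers with the given window and stride.

    Token i is ``bases[i*stride : i*stride + k]`` for
    i = 0 .. floor((l-k)/stride), so the token count is
    floor((l-k)/stride) + 1. A sequence shorter than k raises
    :class:`EmptySentenceError` rather than returning an empty sentence.
    """
    if isinstance(bases, (DNASequence, CombinedSequence)):
        if source_id is None:
            source_id = getattr(bases, "id", None) or getattr(bases, "source_id")
        bases = bases.bases
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    l = len(bases)
    if l < k:
        raise EmptySentenceError(
            f"sequence of length {l} is shorter than k={k}: no tokens can be produced"
        )
    tokens = tuple(bases[i : i + k] for i in range(0, l - k + 1, stride))
    return KmerSentence(tokens=tokens, k=k, stride=stride, source_id=source_id or "")


# ---------------------------------------------------------------------------
# FASTA and corpus I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[DNASequence]:
    """Read a (possibly wrapped) multi-record FASTA into validated sequences."""
    records = [
        DNASequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Iterable[DNASequence], path: str | Path) -> None:
    records = (SeqRecord(Seq(s.bases), id=s.id, description="") for s in sequences)
    SeqIO.write(records, str(path), "fasta")


def write_corpus(sentences: Iterable[KmerSentence], path: str | Path) -> None:
    """Write one sentence per line, tokens space-separated (plain text)."""
    with open(path, "w") as fh:
        for sent in sentences:
            fh.write(" ".join(sent.tokens) + "\n")


def read_corpus(path: str | Path, k: int, stride: int) -> list[KmerSentence]:
    sentences = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            tokens = tuple(line.split())
            if tokens:
                sentences.append(
                    KmerSentence(tokens=tokens, k=k, stride=stride, source_id=f"line{i}")
                )
    return sentences
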