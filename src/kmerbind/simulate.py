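"""Synthetic motif-implanted datasets for end-to-end testing and benchmarks.

Real positives are ChIP-seq peak windows enriched for a transcription
factor's binding motif; real negatives are GC- and length-matched
background. The generator emulates exactly that structure: positives are
i.i.d. background sequences with one motif instance sampled from a
position weight matrix (PWM) implanted at a random offset — on the
forward or reverse-complement strand with equal probability — and
negatives are background draws GC-matched to a designated positive
partner. What it deliberately does not emulate: genomic repeat structure,
multi-occurrence motifs, chromatin context, and peak-calling noise.

The bundled default motif is a 12-column PWM with per-column consensus
probability 0.85: strong enough for the default network to learn within
20 epochs at n=500, weak enough that representation choices still matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .datasets import LabeledDataset, gc_content, generate_matched_negatives
from .seqrep import DNASequence, inverse_complement, write_fasta

_BASES = np.array(list("ACGT"))
_BASE_TO_COL = {b: i for i, b in enumerate("ACGT")}

DEFAULT_MOTIF_CONSENSUS = "TGACGTCATGCA"


@dataclass(frozen=True)
class MotifModel:
    """Position weight matrix: per-position nucleotide probabilities (L x 4)."""

    pwm: np.ndarray
    name: str = "motif"

    def __post_init__(self) -> None:
        pwm = np.asarray(self.pwm, dtype=np.float64)
        object.__setattr__(self, "pwm", pwm)
        if pwm.ndim != 2 or pwm.shape[1] != 4:
            raise ValueError("PWM must have shape (motif_length, 4)")
        if (pwm < 0).any() or not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must be non-negative and sum to 1")

    def __len__(self) -> int:
        return self.pwm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[self.pwm.argmax(axis=1)])

    @classmethod
    def from_consensus(cls, consensus: str, major: float = 0.85,
                       name: str = "motif") -> "MotifModel":
        """PWM giving probability ``major`` to the consensus base per column."""
        minor = (1.0 - major) / 3.0
        pwm = np.full((len(consensus), 4), minor)
        for i, b in enumerate(consensus):
            pwm[i, _BASE_TO_COL[b]] = major
        return cls(pwm=pwm, name=name)


def default_motif() -> MotifModel:
    return MotifModel.from_consensus(DEFAULT_MOTIF_CONSENSUS, major=0.85,
                                     name="default12")


@dataclass
class SimConfig:
    n_pos: int = 500
    ratio: int = 1
    seq_length: int = 200
    gc: float = 0.5
    motif: MotifModel = field(default_factory=default_motif)
    position_law: Literal["uniform", "center"] = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1:
            raise ValueError("n_pos must be >= 1")
        if self.ratio not in (1, 2, 3):
            raise ValueError(f"ratio must be 1, 2 or 3, got {self.ratio}")
        if self.seq_length < len(self.motif):
            raise ValueError("seq_length must be at least the motif length")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def sample_background_bases(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. bases with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def sample_background(length: int, gc: float,
                      seed: int | np.random.Generator = 0,
                      seq_id: str = "bg") -> DNASequence:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return DNASequence(seq_id, sample_background_bases(length, gc, rng))


def sample_motif_instance(motif: MotifModel, rng: np.random.Generator) -> str:
    """Draw one motif instance column-wise from the PWM."""
    return "".join(rng.choice(_BASES, p=row) for row in motif.pwm)


def implant_motif(
    seq: DNASequence,
    motif: MotifModel,
    position_law: Literal["uniform", "center"] = "uniform",
    seed: int | np.random.Generator = 0,
) -> tuple[DNASequence, int, str]:
    """Replace a window of ``seq`` with a sampled motif instance.

    With probability 0.5 the reverse complement of the instance is
    implanted (a motif on the opposite strand reads as its reverse
    complement on this one). Returns (new sequence, implant start,
    strand '+'/'-'); the output length equals the input length.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = len(motif)
    if len(seq) < m:
        raise ValueError("sequence shorter than motif")
    hi = len(seq) - m
    if position_law == "uniform":
        start = int(rng.integers(0, hi + 1))
    elif position_law == "center":
        # binomial spread around the central offset
        start = int(np.clip(rng.binomial(hi, 0.5), 0, hi)) if hi > 0 else 0
    else:
        raise ValueError(f"unknown position law {position_law!r}")
    instance = sample_motif_instance(motif, rng)
    strand = "+"
    if rng.random() < 0.5:
        instance = inverse_complement(DNASequence("m", instance)).bases
        strand = "-"
    bases = seq.bases[:start] + instance + seq.bases[start + m :]
    return DNASequence(seq.id, bases), start, strand


def generate_dataset(config: SimConfig) -> tuple[LabeledDataset, pd.DataFrame]:
    """Full synthetic dataset plus the ground-truth implant table.

    Positives: background draws with one PWM instance implanted.
    Negatives: fresh background draws (no implant) GC-matched to a
    designated positive partner via the rejection sampler, ``ratio`` per
    positive. The ground-truth table lists every implant (id, start,
    strand); negatives never appear in it.
    """
    rng = np.random.default_rng(config.seed)
    positives: list[DNASequence] = []
    truth_rows = []
    for i in range(config.n_pos):
        bg = DNASequence(f"pos_{i}",
                         sample_background_bases(config.seq_length, config.gc, rng))
        seq, start, strand = implant_motif(bg, config.motif, config.position_law, rng)
        positives.append(seq)
        truth_rows.append({"id": seq.id, "implant_start": start, "strand": strand})

    negatives = generate_matched_negatives(
        positives,
        ratio=config.ratio,
        sampler="background",
        background=lambda length, gc, r: sample_background_bases(length, gc, r),
        gc_tolerance=0.02,
        seed=rng,
    )
    records = [(s, 1) for s in positives] + [(s, 0) for s in negatives]
    dataset = LabeledDataset(
        records=records,
        ratio=config.ratio,
        meta={
            "generator": "pwm-implant",
            "motif": config.motif.name,
            "motif_consensus": config.motif.consensus,
            "seq_length": config.seq_length,
            "gc": config.gc,
            "position_law": config.position_law,
            "seed": config.seed,
        },
    )
    return dataset, pd.DataFrame(truth_rows)


def write_simulated(dataset: LabeledDataset, truth: pd.DataFrame,
                    outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
    """Write paired FASTA + manifest (datasets-module schema) + ground truth."""
    from .datasets import write_dataset

    paths = write_dataset(dataset, outdir, prefix=prefix)
    truth_path = Path(outdir) / f"{prefix}_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
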