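"""Labeled dataset construction: peak extraction, matched negatives, CV splits.

Positive examples are fixed-width (default 200 bp) genomic windows centered
on the highest-scoring ChIP-seq peaks. Negatives must match the positives'
length and GC content, otherwise the classifier can separate the classes on
composition alone; each negative is tied to a designated positive partner
whose GC content it matches. Two samplers are available:

* ``shuffle`` (default): a mononucleotide shuffle of the partner positive —
  exact GC and length match; any repeat structure is destroyed.
* ``background``: rejection sampling from a background source (a pool of
  sequences or a generating callable) until the candidate's GC content is
  within ``gc_tolerance`` of the partner's.

Evaluation uses stratified 3-fold cross-validation with 1/8 of each
training portion held out as a validation set for model selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .seqrep import DNASequence, write_fasta

logger = logging.getLogger(__name__)

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "summit",
]


@dataclass
class LabeledDataset:
    """Fixed-length sequences with binary labels (1 = bound, 0 = unbound)."""

    records: list[tuple[DNASequence, int]]
    ratio: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(seq) for seq, _ in self.records}
        if len(lengths) > 1:
            raise ValueError(f"dataset mixes sequence lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[DNASequence]:
        return [seq for seq, _ in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab in self.records], dtype=np.int64)


@dataclass
class FoldSplit:
    """Cross-validation fold assignment plus per-fold validation masks.

    ``folds[i]`` is the fold of record i. When fold f is held out as the
    test set, ``val_masks[f]`` marks the records (all outside fold f) that
    serve as the validation set; the rest of the non-f records are the
    training set. The validation mask is drawn per held-out fold because
    the training portion differs for each.
    """

    folds: np.ndarray
    val_masks: dict[int, np.ndarray]
    n_folds: int
    seed: int

    def train_val_test(self, test_fold: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Index arrays (train, val, test) for one held-out fold."""
        test = np.flatnonzero(self.folds == test_fold)
        val = np.flatnonzero(self.val_masks[test_fold])
        train_mask = (self.folds != test_fold) & ~self.val_masks[test_fold]
        return np.flatnonzero(train_mask), val, test


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------

def load_genome(path: str | Path):
    """Open an indexed genome FASTA (pyfaidx; creates the .fai if absent)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    """Read a BED/narrowPeak file (0-based half-open) into a DataFrame.

    Plain BED with fewer columns is accepted; missing narrowPeak columns
    are filled (signalValue falls back to the score column, summit to -1).
    """
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    df.columns = NARROWPEAK_COLUMNS[: df.shape[1]]
    if "signalValue" not in df.columns:
        df["signalValue"] = df["score"] if "score" in df.columns else 0.0
    if "summit" not in df.columns:
        df["summit"] = -1
    return df


def extract_positives(
    peaks: pd.DataFrame,
    genome,
    top_n: int,
    width: int = 200,
) -> list[DNASequence]:
    """Extract fixed-width windows around the ``top_n`` highest-scoring peaks.

    ``genome`` is an indexed FASTA (a ``pyfaidx.Fasta`` or any mapping from
    chromosome name to sliceable sequence). Peaks are ranked by
    signalValue, ties broken by (chrom, start) for determinism. Each window
    is centered on the summit when a non-negative summit offset is present,
    otherwise on the interval midpoint: [center - width//2, center +
    width//2). Windows extending past a chromosome end are skipped with a
    warning; an unknown chromosome is an error.
    """
    ranked = peaks.sort_values(
        ["signalValue", "chrom", "start"], ascending=[False, True, True]
    )
    if top_n > len(ranked):
        logger.warning(
            "top_n=%d exceeds peak count %d; returning all peaks", top_n, len(ranked)
        )
        top_n = len(ranked)
    out: list[DNASequence] = []
    for _, row in ranked.head(top_n).iterrows():
        chrom = str(row["chrom"])
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} not present in genome FASTA")
        summit = int(row.get("summit", -1))
        if summit >= 0:
            center = int(row["start"]) + summit
        else:
            center = (int(row["start"]) + int(row["end"])) // 2
        lo, hi = center - width // 2, center - width // 2 + width
        chrom_seq = genome[chrom]
        if lo < 0 or hi > len(chrom_seq):
            logger.warning(
                "window [%d, %d) on %s outside chromosome bounds [0, %d); skipped",
                lo, hi, chrom, len(chrom_seq),
            )
            continue
        bases = str(chrom_seq[lo:hi]).upper()
        out.append(DNASequence(f"{chrom}:{lo}-{hi}", bases))
    return out


# ---------------------------------------------------------------------------
# GC matching
# ---------------------------------------------------------------------------

def gc_content(seq: DNASequence | str) -> float:
    """Fraction of G/C among non-N bases; an all-N sequence is undefined."""
    bases = seq.bases if isinstance(seq, DNASequence) else seq
    denom = len(bases) - bases.count("N")
    if denom == 0:
        raise ValueError("GC content undefined for an all-N sequence")
    return (bases.count("G") + bases.count("C")) / denom


BackgroundSource = Sequence[DNASequence] | Callable[[int, float, np.random.Generator], str]


def generate_matched_negatives(
    positives: Sequence[DNASequence],
    ratio: int = 1,
    sampler: Literal["shuffle", "background"] = "shuffle",
    background: BackgroundSource | None = None,
    gc_tolerance: float = 0.02,
    max_attempts: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[DNASequence]:
    """Generate ``ratio`` negatives per positive, matched on length and GC.

    Every positive is partner to exactly ``ratio`` negatives. The
    ``shuffle`` sampler permutes the partner's bases (GC match exact); the
    ``background`` sampler rejection-samples from ``background`` — either a
    pool of sequences (random windows are cut from pool members long
    enough) or a callable ``(length, target_gc, rng) -> bases`` — until the
    candidate's GC is within ``gc_tolerance`` of the partner's. If
    ``max_attempts`` draws fail, the tolerance is doubled once with a
    warning; a second failure is an error. A negative identical to any
    positive is resampled.
    """
    if not positives:
        raise ValueError("positives must be non-empty")
    lengths = {len(p) for p in positives}
    if len(lengths) > 1:
        raise ValueError(f"positives mix lengths: {sorted(lengths)}")
    if sampler == "background" and background is None:
        raise ValueError("background sampler requires a background source")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positive_bases = {p.bases for p in positives}
    width = lengths.pop()

    def draw(partner: DNASequence, tol: float, attempts: int) -> str | None:
        target_gc = gc_content(partner)
        for _ in range(attempts):
            if sampler == "shuffle":
                arr = np.frombuffer(partner.bases.encode(), dtype="S1")
                cand = rng.permutation(arr).tobytes().decode()
            elif callable(background):
                cand = background(width, target_gc, rng)
            else:
                pool_ok = [s for s in background if len(s) >= width]
                if not pool_ok:
                    raise ValueError("no background sequence is long enough")
                src = pool_ok[rng.integers(len(pool_ok))]
                start = rng.integers(len(src) - width + 1)
                cand = src.bases[start : start + width]
            if cand in positive_bases:
                continue
            if sampler == "shuffle" or abs(gc_content(cand) - target_gc) <= tol:
                return cand
        return None

    negatives: list[DNASequence] = []
    for p_idx, partner in enumerate(positives):
        for j in range(ratio):
            cand = draw(partner, gc_tolerance, max_attempts)
            if cand is None:
                warnings.warn(
                    f"could not match GC of {partner.id!r} within {gc_tolerance} "
                    f"after {max_attempts} attempts; relaxing tolerance to "
                    f"{2 * gc_tolerance}"
                )
                cand = draw(partner, 2 * gc_tolerance, max_attempts)
                if cand is None:
                    raise RuntimeError(
                        f"background sampler failed for positive {partner.id!r} "
                        f"even at relaxed tolerance {2 * gc_tolerance}"
                    )
            negatives.append(DNASequence(f"neg_{p_idx}_{j}", cand))
    return negatives


# ---------------------------------------------------------------------------
# fold splitting
# ---------------------------------------------------------------------------

def split_folds(
    dataset: LabeledDataset,
    n_folds: int = 3,
    val_frac: float = 1 / 8,
    seed: int = 0,
) -> FoldSplit:
    """Stratified fold assignment plus per-held-out-fold validation masks.

    Folds preserve the class ratio (within one record). For each held-out
    fold, floor(val_frac * |training portion|) records are drawn at random
    from the training portion as the validation set.
    """
    n = len(dataset)
    if n < n_folds:
        raise ValueError(f"dataset has {n} records, fewer than {n_folds} folds")
    labels = dataset.labels
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(n, dtype=np.int64)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
        folds[test_idx] = f
    rng = np.random.default_rng(seed)
    val_masks: dict[int, np.ndarray] = {}
    for f in range(n_folds):
        train_idx = np.flatnonzero(folds != f)
        n_val = int(len(train_idx) * val_frac)
        chosen = rng.choice(train_idx, size=n_val, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[chosen] = True
        val_masks[f] = mask
    return FoldSplit(folds=folds, val_masks=val_masks, n_folds=n_folds, seed=seed)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def write_dataset(
    dataset: LabeledDataset,
    outdir: str | Path,
    split: FoldSplit | None = None,
    prefix: str = "dataset",
) -> dict[str, Path]:
    """Write paired FASTA files (pos/neg) and a TSV manifest.

    The manifest has one row per record: id, label, fold (-1 if no split),
    and one val_fold_f flag column per held-out fold.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pos = [seq for seq, lab in dataset.records if lab == 1]
    neg = [seq for seq, lab in dataset.records if lab == 0]
    paths = {
        "pos_fasta": outdir / f"{prefix}_pos.fa",
        "neg_fasta": outdir / f"{prefix}_neg.fa",
        "manifest": outdir / f"{prefix}_manifest.tsv",
    }
    write_fasta(pos, paths["pos_fasta"])
    write_fasta(neg, paths["neg_fasta"])
    rows = {
        "id": [seq.id for seq, _ in dataset.records],
        "label": [lab for _, lab in dataset.records],
        "fold": split.folds if split is not None else -1,
    }
    if split is not None:
        for f in range(split.n_folds):
            rows[f"val_fold_{f}"] = split.val_masks[f].astype(int)
    pd.DataFrame(rows).to_csv(paths["manifest"], sep="\t", index=False)
    return paths
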