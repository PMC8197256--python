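"""Peak extraction, GC matching, and cross-validation splits."""

import numpy as np
import pandas as pd
import pytest

from kmerbind.datasets import (
    LabeledDataset,
    extract_positives,
    gc_content,
    generate_matched_negatives,
    load_genome,
    read_narrowpeak,
    split_folds,
    write_dataset,
)
from kmerbind.seqrep import DNASequence


@pytest.fixture
def toy_genome(rng):
    # dict-of-strings genome stands in for an indexed FASTA
    return {
        "chr1": "".join(rng.choice(list("ACGT"), size=10_000)),
        "chr2": "".join(rng.choice(list("ACGT"), size=5_000)),
    }


def _peaks(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "signalValue", "pValue", "qValue", "summit"],
    )


class TestExtractPositives:
    def test_top_n_selection_and_width(self, toy_genome, rng):
        rows = [
            ("chr1", int(s), int(s) + 400, f"p{i}", 0, ".", float(i), -1, -1, -1)
            for i, s in enumerate(rng.integers(200, 9000, size=20))
        ]
        out = extract_positives(_peaks(rows), toy_genome, top_n=5, width=200)
        assert len(out) == 5
        assert all(len(s) == 200 for s in out)

    def test_midpoint_window_coordinates_by_hand(self, toy_genome):
        # peak [1000, 1400), no summit: center 1200, window [1100, 1300)
        peaks = _peaks([("chr1", 1000, 1400, "p", 0, ".", 5.0, -1, -1, -1)])
        (seq,) = extract_positives(peaks, toy_genome, top_n=1, width=200)
        assert seq.id == "chr1:1100-1300"
        assert seq.bases == toy_genome["chr1"][1100:1300].upper()

    def test_summit_centered_window(self, toy_genome):
        # summit offset 50 from start 1000: center 1050, window [950, 1150)
        peaks = _peaks([("chr1", 1000, 1400, "p", 0, ".", 5.0, -1, -1, 50)])
        (seq,) = extract_positives(peaks, toy_genome, top_n=1, width=200)
        assert seq.id == "chr1:950-1150"

    def test_out_of_bounds_skipped(self, toy_genome, caplog):
        peaks = _peaks(
            [
                ("chr1", 0, 100, "edge", 0, ".", 9.0, -1, -1, -1),
                ("chr1", 1000, 1400, "ok", 0, ".", 5.0, -1, -1, -1),
            ]
        )
        out = extract_positives(peaks, toy_genome, top_n=2, width=200)
        assert len(out) == 1

    def test_missing_chromosome_is_error(self, toy_genome):
        peaks = _peaks([("chrX", 1000, 1400, "p", 0, ".", 5.0, -1, -1, -1)])
        with pytest.raises(KeyError):
            extract_positives(peaks, toy_genome, top_n=1)

    def test_top_n_clamped_with_warning(self, toy_genome, caplog):
        peaks = _peaks([("chr1", 1000, 1400, "p", 0, ".", 5.0, -1, -1, -1)])
        out = extract_positives(peaks, toy_genome, top_n=10, width=200)
        assert len(out) == 1

    def test_indexed_genome_fasta_extraction(self, tmp_path, rng):
        bases = "".join(rng.choice(list("ACGT"), size=2000))
        fa = tmp_path / "genome.fa"
        fa.write_text(">chr1\n" + "\n".join(bases[i:i+60] for i in range(0, 2000, 60)) + "\n")
        genome = load_genome(fa)
        peaks = _peaks([("chr1", 500, 900, "p", 0, ".", 5.0, -1, -1, -1)])
        (seq,) = extract_positives(peaks, genome, top_n=1, width=100)
        assert seq.bases == bases[650:750]

    def test_narrowpeak_reader(self, tmp_path):
        path = tmp_path / "peaks.narrowPeak"
        path.write_text("chr1\t100\t500\tp1\t0\t.\t7.5\t-1\t-1\t40\n")
        df = read_narrowpeak(path)
        assert df.loc[0, "signalValue"] == 7.5
        assert df.loc[0, "summit"] == 40


class TestGcContent:
    @pytest.mark.parametrize(
        "bases,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5)]
    )
    def test_examples(self, bases, expected):
        assert gc_content(DNASequence("x", bases)) == expected

    def test_n_excluded_from_both_sides(self):
        assert gc_content(DNASequence("x", "GCNN")) == 1.0

    def test_all_n_undefined(self):
        with pytest.raises(ValueError):
            gc_content(DNASequence("x", "NNN"))


class TestMatchedNegatives:
    def test_counts_and_length(self, random_sequences):
        pos = random_sequences(20, 200)
        neg = generate_matched_negatives(pos, ratio=2, seed=0)
        assert len(neg) == 40
        assert all(len(s) == 200 for s in neg)

    def test_shuffle_sampler_exact_gc(self, random_sequences):
        pos = random_sequences(10, 100)
        neg = generate_matched_negatives(pos, ratio=1, sampler="shuffle", seed=0)
        for p, n in zip(pos, neg):
            assert sorted(p.bases) == sorted(n.bases)

    def test_background_sampler_mean_gc_gap(self, rng):
        """Monte-Carlo check of the GC-matching loop at tolerance 0.02."""
        pos = [
            DNASequence(f"p{i}", "".join(rng.choice(list("ACGT"), size=100)))
            for i in range(300)
        ]

        def bg(length, gc, r):
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            return "".join(r.choice(list("ACGT"), size=length, p=p))

        neg = generate_matched_negatives(
            pos, ratio=1, sampler="background", background=bg,
            gc_tolerance=0.02, seed=1
        )
        gap = abs(
            np.mean([gc_content(p) for p in pos]) - np.mean([gc_content(n) for n in neg])
        )
        assert gap < 0.01
        for p, n in zip(pos, neg):
            assert abs(gc_content(p) - gc_content(n)) <= 0.02

    def test_no_negative_equals_a_positive(self):
        # short sequences make collisions likely; the sampler must avoid them
        pos = [DNASequence(f"p{i}", b) for i, b in enumerate(["AACC", "CCAA", "ACAC"])]
        neg = generate_matched_negatives(pos, ratio=1, sampler="shuffle", seed=0)
        assert not ({n.bases for n in neg} & {p.bases for p in pos})

    def test_pool_background_source(self, random_sequences):
        pos = random_sequences(5, 50)
        pool = random_sequences(20, 300)
        neg = generate_matched_negatives(
            pos, ratio=1, sampler="background", background=pool,
            gc_tolerance=0.05, seed=0
        )
        assert len(neg) == 5 and all(len(n) == 50 for n in neg)

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError):
            generate_matched_negatives([], ratio=1)


def _dataset(n_pos, n_neg, length=30, seed=0):
    rng = np.random.default_rng(seed)
    mk = lambda i: DNASequence(f"r{i}", "".join(rng.choice(list("ACGT"), size=length)))
    records = [(mk(i), 1) for i in range(n_pos)] + [
        (mk(n_pos + i), 0) for i in range(n_neg)
    ]
    return LabeledDataset(records=records, ratio=max(1, n_neg // max(n_pos, 1)))


class TestLabeledDataset:
    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            LabeledDataset(
                records=[(DNASequence("a", "ACG"), 1), (DNASequence("b", "ACGT"), 0)],
                ratio=1,
            )


class TestSplitFolds:
    def test_folds_partition_and_sizes(self):
        ds = _dataset(150, 150)
        split = split_folds(ds, n_folds=3, seed=0)
        sizes = np.bincount(split.folds, minlength=3)
        assert sizes.sum() == 300
        assert all(s == 100 for s in sizes)

    def test_validation_fraction_floor(self):
        ds = _dataset(180, 180)  # training portion per fold = 240
        split = split_folds(ds, n_folds=3, val_frac=1 / 8, seed=0)
        for f in range(3):
            _, val_idx, _ = split.train_val_test(f)
            assert len(val_idx) == 30

    def test_stratification_within_one_record(self):
        ds = _dataset(100, 200)
        split = split_folds(ds, n_folds=3, seed=1)
        labels = ds.labels
        for f in range(3):
            fold_labels = labels[split.folds == f]
            assert abs(fold_labels.sum() - 100 / 3) <= 1

    def test_same_seed_identical_split(self):
        ds = _dataset(60, 60)
        s1, s2 = split_folds(ds, seed=9), split_folds(ds, seed=9)
        assert np.array_equal(s1.folds, s2.folds)
        for f in range(3):
            assert np.array_equal(s1.val_masks[f], s2.val_masks[f])

    def test_train_val_test_disjoint_and_exhaustive(self):
        ds = _dataset(50, 50)
        split = split_folds(ds, seed=2)
        for f in range(3):
            tr, va, te = split.train_val_test(f)
            parts = np.concatenate([tr, va, te])
            assert len(parts) == len(set(parts)) == 100

    def test_val_drawn_from_training_folds_only(self):
        ds = _dataset(50, 50)
        split = split_folds(ds, seed=3)
        for f in range(3):
            assert not np.any(split.val_masks[f] & (split.folds == f))

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_folds(_dataset(1, 1), n_folds=3)


class TestWriteDataset:
    def test_fasta_pair_and_manifest(self, tmp_path):
        ds = _dataset(6, 6)
        split = split_folds(ds, seed=0)
        paths = write_dataset(ds, tmp_path, split=split)
        manifest = pd.read_csv(paths["manifest"], sep="\t")
        assert len(manifest) == 12
        assert set(manifest["label"]) == {0, 1}
        assert paths["pos_fasta"].exists() and paths["neg_fasta"].exists()
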