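import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funcmotif.dataset import (
    GC_BIN_WIDTH,
    DatasetConfig,
    EncodingError,
    SamplingError,
    assign_splits,
    build_positives,
    encode_onehot,
    gc_fraction,
    sample_gc_matched_negatives,
)
from funcmotif.intervals import GenomicInterval, PeakRecord, reverse_complement
from funcmotif.synthetic import SyntheticGenomeConfig, generate_genome


def _peak(chrom, start, tags, pid="p"):
    return PeakRecord(GenomicInterval(chrom, start, start + 300), pid, tags)


@pytest.fixture(scope="module")
def genome():
    lengths = {f"chr{i}": 30_000 for i in range(1, 10)}
    lengths.update(chrX=10_000, chrY=5_000)
    return generate_genome(SyntheticGenomeConfig(lengths, 0.42, 17))


class TestBuildPositives:
    def test_tag_threshold_is_inclusive_at_32(self, genome):
        peaks = [
            _peak("chr1", 1000, t, f"p{t}") for t in (10, 31, 32, 100)
        ]
        kept = build_positives(peaks, genome)
        assert len(kept) == 2
        assert all(len(e.sequence) == 300 and e.label == 1 for e in kept)

    def test_sex_chromosomes_excluded_regardless_of_tags(self, genome):
        kept = build_positives([_peak("chrX", 1000, 500)], genome)
        assert kept == []

    def test_empty_input(self, genome):
        assert build_positives([], genome) == []

    def test_window_is_centred_on_peak_midpoint(self, genome):
        peak = PeakRecord(GenomicInterval("chr1", 1000, 1500), "wide", 50)
        (ex,) = build_positives([peak], genome)
        assert (ex.interval.start, ex.interval.end) == (1100, 1400)
        assert ex.sequence == genome["chr1"][1100:1400]

    def test_window_past_chromosome_end_dropped(self, genome):
        kept = build_positives([_peak("chr1", 29_900, 99, "edge")], genome)
        assert kept == []


class TestNegativeSampling:
    def test_counts_and_labels_balance(self, genome):
        peaks = [_peak("chr1", 1000 + 400 * i, 50, f"p{i}") for i in range(50)]
        positives = build_positives(peaks, genome)
        negatives = sample_gc_matched_negatives(genome, positives)
        assert len(negatives) == len(positives) == 50
        assert all(n.label == 0 for n in negatives)

    def test_gc_matched_bin_for_bin_and_no_positive_overlap(self, genome):
        peaks = [_peak("chr2", 500 + 400 * i, 40, f"q{i}") for i in range(60)]
        positives = build_positives(peaks, genome)
        negatives = sample_gc_matched_negatives(genome, positives)
        for pos, neg in zip(positives, negatives):
            assert abs(gc_fraction(neg.sequence) - gc_fraction(pos.sequence)) \
                <= GC_BIN_WIDTH
            assert neg.interval.chrom not in ("chrX", "chrY")
            assert not any(
                neg.interval.overlaps(p.interval) for p in positives
            )
        # distribution-level agreement: because matching is bin-for-bin, the
        # KS distance is bounded by the largest single-bin share of positives
        pos_gc = np.sort([gc_fraction(p.sequence) for p in positives])
        neg_gc = np.sort([gc_fraction(n.sequence) for n in negatives])
        grid = np.linspace(0, 1, 201)
        ks = np.max(np.abs(
            np.searchsorted(pos_gc, grid) / pos_gc.size
            - np.searchsorted(neg_gc, grid) / neg_gc.size
        ))
        bins = (pos_gc / GC_BIN_WIDTH).astype(int)
        max_share = np.max(np.bincount(bins)) / pos_gc.size
        assert ks <= max_share + 1e-12

    def test_deterministic_given_seed(self, genome):
        peaks = [_peak("chr3", 1000 + 400 * i, 40, f"r{i}") for i in range(20)]
        positives = build_positives(peaks, genome)
        a = sample_gc_matched_negatives(genome, positives)
        b = sample_gc_matched_negatives(genome, positives)
        assert a == b

    def test_infeasible_bin_raises(self, genome):
        fake = [
            type(p)(p.interval, "G" * 300, 1, p.split)
            for p in build_positives([_peak("chr1", 1000, 50)], genome)
        ]
        with pytest.raises(SamplingError):
            sample_gc_matched_negatives(genome, fake)

    def test_empty_positive_set_rejected(self, genome):
        with pytest.raises(ValueError):
            sample_gc_matched_negatives(genome, [])


class TestSplits:
    @pytest.mark.parametrize(
        "chrom,expected",
        [("chr8", "validation"), ("chr9", "test"), ("chr1", "train")],
    )
    def test_split_is_a_function_of_chromosome(self, genome, chrom, expected):
        peaks = [_peak(chrom, 1000, 64)]
        (ex,) = assign_splits(build_positives(peaks, genome))
        assert ex.split == expected

    def test_partition_is_exhaustive_and_disjoint(self, genome):
        peaks = [
            _peak(f"chr{c}", 400 * i + 200, 40, f"s{c}_{i}")
            for c in range(1, 10)
            for i in range(5)
        ]
        examples = assign_splits(build_positives(peaks, genome))
        assert all(ex.split in ("train", "validation", "test") for ex in examples)
        for ex in examples:
            expected = {
                "chr8": "validation", "chr9": "test"
            }.get(ex.interval.chrom, "train")
            assert ex.split == expected

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            DatasetConfig(window_length=0)


class TestOneHot:
    def test_canonical_bases_are_identity(self):
        assert np.array_equal(encode_onehot("ACGT"), np.eye(4))

    def test_n_encodes_as_quarter(self):
        assert np.array_equal(encode_onehot("N"), [[0.25] * 4])

    def test_illegal_character_raises(self):
        with pytest.raises(EncodingError):
            encode_onehot("ACGU")

    @settings(deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=20))
    def test_revcomp_identity(self, seq):
        # encode(revcomp(s)) == row-reverse + column-swap of encode(s)
        enc = encode_onehot(seq)
        rc = encode_onehot(reverse_complement(seq))
        assert np.array_equal(rc, enc[::-1, ::-1])
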