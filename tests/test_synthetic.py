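import numpy as np
import pytest

from funcmotif.intervals import reverse_complement
from funcmotif.synthetic import (
    GenerationError,
    SyntheticGenomeConfig,
    SyntheticPeakSetConfig,
    generate_genome,
    plant_enhancers,
    read_fasta,
    read_peaks,
    read_truth,
    write_fixture,
)


def small_genome(seed=0, gc=0.42, n=6, length=20_000):
    lengths = {f"chr{i}": length for i in range(1, n + 1)}
    return generate_genome(SyntheticGenomeConfig(lengths, gc, seed))


def test_zero_gc_yields_at_only():
    g = generate_genome(SyntheticGenomeConfig({"chrT": 10}, 0.0, 5))
    assert set(g["chrT"]) <= {"A", "T"}
    assert len(g["chrT"]) == 10


def test_gc_fraction_converges_at_large_n():
    g = generate_genome(SyntheticGenomeConfig({"chrT": 100_000}, 0.5, 1))
    seq = g["chrT"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.5) <= 0.02


def test_identical_config_is_byte_identical():
    cfg = SyntheticGenomeConfig({"chrA": 5000, "chrB": 3000}, 0.42, 9)
    assert generate_genome(cfg) == generate_genome(cfg)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SyntheticGenomeConfig({"chrT": 100}, 1.5, 0)
    with pytest.raises(ValueError):
        SyntheticGenomeConfig({"chrT": 0}, 0.5, 0)


def test_planting_count_conservation(pwms):
    genome = small_genome()
    cfg = SyntheticPeakSetConfig(
        n_active_peaks=10, n_inactive_peaks=5, motifs_per_active_peak=1, seed=2
    )
    peaks, truth = plant_enhancers(genome, pwms, cfg)
    assert len(peaks) == 15
    assert len(truth) == 10 * len(pwms) * 1  # n_active x |pwms| x instances


def test_no_planting_leaves_genome_unchanged(pwms):
    genome = small_genome(seed=4)
    pristine = dict(genome)
    cfg = SyntheticPeakSetConfig(
        n_active_peaks=5, n_inactive_peaks=5, motifs_per_active_peak=0, seed=3
    )
    peaks, truth = plant_enhancers(genome, pwms, cfg)
    assert truth == []
    assert genome == pristine


def test_truth_matches_genome_with_strand_contract(pwms, tmp_path):
    genome = small_genome(seed=7)
    cfg = SyntheticPeakSetConfig(
        n_active_peaks=8, n_inactive_peaks=4, motifs_per_active_peak=1, seed=7
    )
    peaks, truth = plant_enhancers(genome, pwms, cfg)
    paths = write_fixture(genome, peaks, truth, tmp_path)
    reread = read_fasta(paths["genome"])
    assert reread == genome
    minus_seen = False
    for t in truth:
        segment = reread[t.interval.chrom][t.interval.start : t.interval.end]
        if t.strand == "+":
            assert segment == t.sampled_sequence
        else:
            minus_seen = True
            assert segment == reverse_complement(t.sampled_sequence)
    assert minus_seen  # both strands exercised at this seed


def test_planted_instances_follow_pwm_composition(pwms):
    # column-wise sampling: the dominant consensus base should dominate
    genome = small_genome(seed=11, n=6, length=50_000)
    cfg = SyntheticPeakSetConfig(
        n_active_peaks=200, n_inactive_peaks=0, motifs_per_active_peak=1, seed=11
    )
    _, truth = plant_enhancers(genome, [pwms[0]], cfg)
    seqs = [t.sampled_sequence for t in truth]
    consensus = pwms[0].consensus()
    for col in range(pwms[0].width):
        observed = sum(s[col] == consensus[col] for s in seqs) / len(seqs)
        expected = pwms[0].freq[col].max()
        assert abs(observed - expected) < 0.12


def test_tag_counts_match_nb_model(pwms):
    genome = small_genome(seed=13, n=8, length=60_000)
    cfg = SyntheticPeakSetConfig(
        n_active_peaks=300, n_inactive_peaks=300,
        motifs_per_active_peak=0, seed=13,
        tag_mean_active=120, tag_mean_inactive=8, tag_dispersion=10,
    )
    peaks, _ = plant_enhancers(genome, pwms, cfg)
    active = [p.tag_count for p in peaks if p.peak_id.startswith("active")]
    inactive = [p.tag_count for p in peaks if p.peak_id.startswith("inactive")]
    assert abs(np.mean(active) - 120) < 15
    assert abs(np.mean(inactive) - 8) < 2
    # overdispersion: variance well above the Poisson mean
    assert np.var(active) > 2 * np.mean(active)


def test_peaks_do_not_overlap(pwms):
    genome = small_genome(seed=5)
    cfg = SyntheticPeakSetConfig(
        n_active_peaks=40, n_inactive_peaks=40, seed=5
    )
    peaks, _ = plant_enhancers(genome, pwms, cfg)
    by_chrom = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p.interval)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end <= b.start


def test_impossible_packing_raises(pwms):
    genome = generate_genome(SyntheticGenomeConfig({"chr1": 900}, 0.5, 1))
    cfg = SyntheticPeakSetConfig(
        n_active_peaks=10, n_inactive_peaks=0, seed=1,
        max_placement_retries=50,
    )
    with pytest.raises(GenerationError):
        plant_enhancers(genome, pwms, cfg)


def test_fixture_roundtrip_and_line_counts(pwms, tmp_path):
    genome = small_genome(seed=21, n=3)
    cfg = SyntheticPeakSetConfig(n_active_peaks=2, n_inactive_peaks=1, seed=21)
    peaks, truth = plant_enhancers(genome, pwms, cfg)
    paths = write_fixture(genome, peaks, truth, tmp_path)
    assert read_peaks(paths["peaks"]) == peaks
    assert read_truth(paths["truth"]) == truth
    assert len(open(paths["peaks"]).readlines()) == 3


def test_empty_peak_file_roundtrip(tmp_path):
    from funcmotif.synthetic import write_peaks

    path = tmp_path / "empty.tsv"
    write_peaks([], path)
    assert read_peaks(path) == []
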