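"""Synthetic genomes, enhancer peaks and planted motifs with known ground truth.

This module emulates the *inputs* of an enhancer-classification study —
a multi-chromosome genome, called accessibility peaks, and per-peak
histone-mark tag counts — at desk scale, so that every downstream stage
(labelling, training, attribution, scanning, functional calling) can be
validated against planted truth instead of external downloads.

The genome is i.i.d. with controllable GC content. "Active" peaks carry
motif instances sampled column-wise from PWM frequencies, written into the
genome on a uniformly random strand at non-overlapping offsets; "inactive"
peaks carry none. Tag counts come from a negative-binomial (mean/dispersion)
model — real ChIP-seq tag counts are overdispersed relative to Poisson, and
mean/dispersion is the minimal realistic stand-in — with a higher mean at
active peaks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, PeakRecord, reverse_complement
from .motifs import BASES, PWMModel

#: default chromosome set: ten 200 kb autosomes plus short sex
#: chromosomes so the sex-chromosome filter is exercisable.
DEFAULT_CHROMOSOME_LENGTHS: Dict[str, int] = {
    **{f"chr{i}": 200_000 for i in range(1, 11)},
    "chrX": 100_000,
    "chrY": 50_000,
}

SEX_CHROMOSOMES = frozenset({"chrX", "chrY"})


class GenerationError(RuntimeError):
    """Raised when a fixture cannot be generated (e.g. impossible packing)."""


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOME_LENGTHS)
    )
    gc_content: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError(f"gc_content must be in [0,1]: {self.gc_content}")
        if not self.chromosome_lengths:
            raise ValueError("chromosome_lengths is empty")
        for chrom, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {chrom}: {length}")


@dataclass(frozen=True)
class SyntheticPeakSetConfig:
    n_active_peaks: int = 650
    n_inactive_peaks: int = 650
    peak_length: int = 300
    motifs_per_active_peak: int = 1
    tag_mean_active: float = 120.0
    tag_mean_inactive: float = 8.0
    tag_dispersion: float = 10.0
    seed: int = 0
    max_placement_retries: int = 1000

    def __post_init__(self) -> None:
        if self.peak_length <= 0:
            raise ValueError("peak_length must be positive")
        if min(self.tag_mean_active, self.tag_mean_inactive) <= 0:
            raise ValueError("tag means must be positive")
        if self.tag_dispersion <= 0:
            raise ValueError("tag_dispersion must be positive")
        if self.motifs_per_active_peak < 0:
            raise ValueError("motifs_per_active_peak must be >= 0")


@dataclass(frozen=True)
class PlantedMotifTruth:
    """Ground truth for one planted motif instance.

    ``sampled_sequence`` is the instance as sampled from the PWM, i.e. the
    motif-strand sequence; on the minus strand the genome carries its
    reverse complement.
    """

    interval: GenomicInterval
    motif_id: str
    strand: str
    sampled_sequence: str


def generate_genome(config: SyntheticGenomeConfig) -> Dict[str, str]:
    """I.i.d. random genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base_bytes = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    genome = {}
    for chrom in sorted(config.chromosome_lengths):
        length = config.chromosome_lengths[chrom]
        draws = rng.choice(4, size=length, p=probs)
        genome[chrom] = base_bytes[draws].tobytes().decode()
    return genome


def _sample_motif_instance(rng: np.random.Generator, pwm: PWMModel) -> str:
    cum = np.cumsum(pwm.freq, axis=1)
    u = rng.random(pwm.width)
    picks = (u[:, None] > cum).sum(axis=1)
    return "".join(BASES[i] for i in picks)


def _place_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    widths: Sequence[int],
    span: int,
    taken: List[Tuple[int, int]],
    retries: int,
    what: str,
) -> List[Tuple[int, int]]:
    """Sample ``n`` non-overlapping [start, start+width) intervals in [0, span)."""
    placed = []
    for k in range(n):
        width = widths[k]
        for _ in range(retries):
            start = int(rng.integers(0, span - width + 1))
            end = start + width
            if all(end <= s or start >= e for s, e in taken):
                taken.append((start, end))
                placed.append((start, end))
                break
        else:
            raise GenerationError(
                f"could not place {what} #{k} after {retries} retries"
            )
    return placed


def plant_enhancers(
    genome: Dict[str, str],
    pwms: Sequence[PWMModel],
    config: SyntheticPeakSetConfig,
) -> Tuple[List[PeakRecord], List[PlantedMotifTruth]]:
    """Plant active/inactive peaks and motif instances; return peaks + truth.

    Mutates ``genome`` in place (active peak sequences receive the sampled
    motif instances). Peaks are placed non-overlapping, chromosomes chosen
    proportionally to length. Tag counts are negative-binomial with the
    configured means and shared dispersion.
    """
    for pwm in pwms:
        if pwm.width >= config.peak_length:
            raise GenerationError(
                f"motif {pwm.motif_id} width {pwm.width} >= peak_length"
            )
    rng = np.random.default_rng(config.seed)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    n_total = config.n_active_peaks + config.n_inactive_peaks
    chrom_choice = rng.choice(len(chroms), size=n_total, p=weights)

    taken_per_chrom: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    peaks: List[PeakRecord] = []
    truth: List[PlantedMotifTruth] = []
    plan_per_peak = [
        (pwm, config.motifs_per_active_peak) for pwm in pwms
    ]

    for i in range(n_total):
        active = i < config.n_active_peaks
        chrom = chroms[chrom_choice[i]]
        span = len(genome[chrom])
        if span < config.peak_length:
            raise GenerationError(f"{chrom} shorter than peak_length")
        (start, end), = _place_nonoverlapping(
            rng, 1, [config.peak_length], span,
            taken_per_chrom[chrom], config.max_placement_retries,
            f"peak on {chrom}",
        )
        mean = config.tag_mean_active if active else config.tag_mean_inactive
        r = config.tag_dispersion
        tags = int(rng.negative_binomial(r, r / (r + mean)))
        peak_id = f"{'active' if active else 'inactive'}_{i}"
        peaks.append(
            PeakRecord(GenomicInterval(chrom, start, end), peak_id, tags)
        )
        if active and config.motifs_per_active_peak > 0:
            seq = list(genome[chrom][start:end])
            local_taken: List[Tuple[int, int]] = []
            for pwm, n_inst in plan_per_peak:
                for _ in range(n_inst):
                    (off, off_end), = _place_nonoverlapping(
                        rng, 1, [pwm.width], config.peak_length,
                        local_taken, config.max_placement_retries,
                        f"motif {pwm.motif_id} in {peak_id}",
                    )
                    instance = _sample_motif_instance(rng, pwm)
                    strand = "+" if rng.random() < 0.5 else "-"
                    planted = (
                        instance if strand == "+"
                        else reverse_complement(instance)
                    )
                    seq[off:off_end] = planted
                    truth.append(
                        PlantedMotifTruth(
                            interval=GenomicInterval(
                                chrom, start + off, start + off_end, strand
                            ),
                            motif_id=pwm.motif_id,
                            strand=strand,
                            sampled_sequence=instance,
                        )
                    )
            genome[chrom] = (
                genome[chrom][:start] + "".join(seq) + genome[chrom][end:]
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    truth.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return peaks, truth


# ---------------------------------------------------------------------------
# fixture I/O (FASTA + BED-like TSV); round-trips losslessly


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(genome[chrom]), id=chrom, description="")
        for chrom in sorted(genome)
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_peaks(peaks: Sequence[PeakRecord], path) -> None:
    """5-column headerless TSV: chrom, start, end, peak_id, tag_count."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.peak_id}\t{p.tag_count}\n"
            )


def read_peaks(path) -> List[PeakRecord]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "peak_id", "tag_count"],
        dtype={"chrom": str, "peak_id": str},
    )
    return [
        PeakRecord(
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            r.peak_id, int(r.tag_count),
        )
        for r in df.itertuples()
    ]


def write_truth(truth: Sequence[PlantedMotifTruth], path) -> None:
    """BED6 + sampled sequence: chrom start end motif_id 0 strand sequence."""
    with open(path, "w") as fh:
        for t in truth:
            fh.write(
                f"{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}"
                f"\t{t.motif_id}\t0\t{t.strand}\t{t.sampled_sequence}\n"
            )


def read_truth(path) -> List[PlantedMotifTruth]:
    entries = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, motif_id, _, strand, seq = (
                line.rstrip("\n").split("\t")
            )
            entries.append(
                PlantedMotifTruth(
                    GenomicInterval(chrom, int(start), int(end), strand),
                    motif_id, strand, seq,
                )
            )
    return entries


def write_fixture(
    genome: Mapping[str, str],
    peaks: Sequence[PeakRecord],
    truth: Sequence[PlantedMotifTruth],
    out_dir,
) -> Dict[str, str]:
    """Persist a complete synthetic fixture; returns the file paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "peaks": os.path.join(out_dir, "peaks.tsv"),
        "truth": os.path.join(out_dir, "truth.bed"),
    }
    write_fasta(genome, paths["genome"])
    write_peaks(peaks, paths["peaks"])
    write_truth(truth, paths["truth"])
    return paths
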