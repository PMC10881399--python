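"""Build the labelled, chromosome-split, one-hot-encoded training set.

Positives are fixed-length windows (default 300 bp, centred on the peak
midpoint) of accessibility peaks with strong histone-acetylation support
(tag count >= 32 by default), with sex chromosomes removed. Negatives are
the same number of GC-content-matched random genomic windows that do not
overlap any positive. Splits are a function of chromosome only: one
held-out chromosome for validation (default chr8), one for testing
(default chr9), everything else trains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, PeakRecord, reverse_complement
from .synthetic import SEX_CHROMOSOMES

logger = logging.getLogger(__name__)

#: width of the GC-fraction histogram bins used for negative matching
GC_BIN_WIDTH = 0.02
#: windows with more than this fraction of N are rejected on both sides
MAX_N_FRACTION = 0.10


class SamplingError(RuntimeError):
    """Raised when a GC-matched negative cannot be found for some bin."""


class EncodingError(ValueError):
    """Raised on non-ACGTN characters in a sequence to encode."""


@dataclass(frozen=True)
class DatasetConfig:
    window_length: int = 300
    min_tag_count: int = 32
    excluded_chromosomes: FrozenSet[str] = field(
        default_factory=lambda: frozenset(SEX_CHROMOSOMES)
    )
    validation_chromosome: str = "chr8"
    test_chromosome: str = "chr9"
    seed: int = 0
    negative_retry_cap: int = 10_000

    def __post_init__(self) -> None:
        # a validation/test chromosome clash is reported by the pipeline's
        # validate_config rather than rejected here, so configs can be
        # constructed, inspected and repaired
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")


@dataclass(frozen=True)
class LabelledExample:
    interval: GenomicInterval
    sequence: str
    label: int
    split: str = "train"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1: {self.label}")
        if self.split not in ("train", "validation", "test"):
            raise ValueError(f"unknown split {self.split!r}")


def gc_fraction(sequence: str) -> float:
    s = sequence.upper()
    return (s.count("G") + s.count("C")) / max(len(s), 1)


def _n_fraction(sequence: str) -> float:
    return sequence.upper().count("N") / max(len(sequence), 1)


def build_positives(
    peaks: Sequence[PeakRecord],
    genome: Mapping[str, str],
    config: DatasetConfig = DatasetConfig(),
) -> List[LabelledExample]:
    """Filter peaks and standardise them to centred fixed-length windows.

    Retains peaks with ``tag_count >= min_tag_count`` on non-excluded
    chromosomes; each survivor becomes a ``window_length`` window centred
    on the peak midpoint, labelled 1. Windows running off a chromosome end
    or dominated by N are dropped with a warning.
    """
    L = config.window_length
    out = []
    for peak in peaks:
        if peak.tag_count < config.min_tag_count:
            continue
        chrom = peak.interval.chrom
        if chrom in config.excluded_chromosomes:
            continue
        if chrom not in genome:
            logger.warning("peak %s on unknown chromosome %s", peak.peak_id, chrom)
            continue
        mid = peak.interval.midpoint()
        start = mid - L // 2
        end = start + L
        if start < 0 or end > len(genome[chrom]):
            logger.warning(
                "peak %s window %s:%d-%d extends past chromosome end; dropped",
                peak.peak_id, chrom, start, end,
            )
            continue
        seq = genome[chrom][start:end]
        if _n_fraction(seq) > MAX_N_FRACTION:
            logger.warning("peak %s window is >10%% N; dropped", peak.peak_id)
            continue
        out.append(
            LabelledExample(GenomicInterval(chrom, start, end), seq, 1)
        )
    return out


def _gc_bin(frac: float) -> int:
    return min(int(frac / GC_BIN_WIDTH), int(1.0 / GC_BIN_WIDTH) - 1)


def sample_gc_matched_negatives(
    genome: Mapping[str, str],
    positives: Sequence[LabelledExample],
    config: DatasetConfig = DatasetConfig(),
    exclude: Optional[Sequence[GenomicInterval]] = None,
) -> List[LabelledExample]:
    """Draw |positives| label-0 windows GC-matched bin-for-bin to the positives.

    Each negative is drawn (uniformly over non-excluded chromosomes,
    length-weighted) until it lands in the same 2%-wide GC bin as its paired
    positive and overlaps no interval in ``exclude`` (default: the positive
    windows themselves). Negatives may overlap each other.
    """
    if not positives:
        raise ValueError("positives must be non-empty")
    if exclude is None:
        exclude = [p.interval for p in positives]
    rng = np.random.default_rng(config.seed)
    L = config.window_length
    chroms = sorted(
        c for c in genome
        if c not in config.excluded_chromosomes and len(genome[c]) >= L
    )
    if not chroms:
        raise SamplingError("no eligible chromosome long enough for a window")

    # index every eligible window start by its GC bin (cumulative-sum rolling
    # GC); sampling uniformly within a bin is distribution-identical to
    # rejection sampling uniformly over all starts, but cannot stall on
    # rare bins
    starts_by_bin: Dict[int, List[np.ndarray]] = {}
    chrom_of: Dict[int, List[int]] = {}
    for ci, chrom in enumerate(chroms):
        seq = genome[chrom].upper()
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = np.cumsum(
            np.concatenate(([0], ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)))
        )
        is_n = np.cumsum(
            np.concatenate(([0], (arr == ord("N")).astype(np.int64)))
        )
        n_starts = len(seq) - L + 1
        gc_counts = is_gc[L:] - is_gc[:-L]
        n_counts = is_n[L:] - is_n[:-L]
        ok = n_counts <= MAX_N_FRACTION * L
        for iv in exclude:
            if iv.chrom == chrom:
                lo = max(0, iv.start - L + 1)
                hi = min(n_starts, iv.end)
                ok[lo:hi] = False
        bins = np.minimum(
            (gc_counts / L / GC_BIN_WIDTH).astype(int),
            int(1.0 / GC_BIN_WIDTH) - 1,
        )
        for b in np.unique(bins[ok]):
            starts_by_bin.setdefault(int(b), []).append(
                np.nonzero(ok & (bins == b))[0]
            )
            chrom_of.setdefault(int(b), []).append(ci)

    flat: Dict[int, np.ndarray] = {}
    flat_chrom: Dict[int, np.ndarray] = {}
    for b, arrays in starts_by_bin.items():
        flat[b] = np.concatenate(arrays)
        flat_chrom[b] = np.concatenate(
            [np.full(a.size, c) for a, c in zip(arrays, chrom_of[b])]
        )

    negatives = []
    for pos in positives:
        target_bin = _gc_bin(gc_fraction(pos.sequence))
        if target_bin not in flat:
            lo, hi = target_bin * GC_BIN_WIDTH, (target_bin + 1) * GC_BIN_WIDTH
            raise SamplingError(
                f"no eligible window in GC bin [{lo:.2f},{hi:.2f})"
            )
        j = int(rng.integers(0, flat[target_bin].size))
        chrom = chroms[int(flat_chrom[target_bin][j])]
        start = int(flat[target_bin][j])
        window = GenomicInterval(chrom, start, start + L)
        negatives.append(
            LabelledExample(window, genome[chrom][start : start + L], 0)
        )
    return negatives


def assign_splits(
    examples: Sequence[LabelledExample],
    config: DatasetConfig = DatasetConfig(),
) -> List[LabelledExample]:
    """Set each example's split purely from its chromosome."""
    out = []
    for ex in examples:
        chrom = ex.interval.chrom
        if chrom == config.validation_chromosome:
            split = "validation"
        elif chrom == config.test_chromosome:
            split = "test"
        else:
            split = "train"
        out.append(replace(ex, split=split))
    return out


_ONEHOT = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 0.0, 1.0),
    "N": (0.25, 0.25, 0.25, 0.25),
}


def encode_onehot(sequence: str) -> np.ndarray:
    """L x 4 one-hot matrix, column order A,C,G,T; N encodes as all-0.25."""
    try:
        return np.array([_ONEHOT[b] for b in sequence.upper()])
    except KeyError as exc:
        raise EncodingError(f"illegal character {exc} in sequence") from exc


def encode_batch(sequences: Sequence[str]) -> np.ndarray:
    return np.stack([encode_onehot(s) for s in sequences])


def build_dataset(
    peaks: Sequence[PeakRecord],
    genome: Mapping[str, str],
    config: DatasetConfig = DatasetConfig(),
) -> List[LabelledExample]:
    """Full labelled dataset: filtered positives + matched negatives, split."""
    positives = build_positives(peaks, genome, config)
    negatives = sample_gc_matched_negatives(genome, positives, config)
    return assign_splits(list(positives) + list(negatives), config)


def split_examples(
    examples: Sequence[LabelledExample],
) -> Dict[str, List[LabelledExample]]:
    out: Dict[str, List[LabelledExample]] = {
        "train": [], "validation": [], "test": []
    }
    for ex in examples:
        out[ex.split].append(ex)
    return out


def write_examples(examples: Sequence[LabelledExample], path) -> None:
    """BED6+2: chrom start end name score strand label split; sequence last."""
    with open(path, "w") as fh:
        for i, ex in enumerate(examples):
            fh.write(
                f"{ex.interval.chrom}\t{ex.interval.start}\t{ex.interval.end}"
                f"\tex_{i}\t0\t.\t{ex.label}\t{ex.split}\t{ex.sequence}\n"
            )


def read_examples(path) -> List[LabelledExample]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, _, _, _, label, split, seq = (
                line.rstrip("\n").split("\t")
            )
            out.append(
                LabelledExample(
                    GenomicInterval(chrom, int(start), int(end)),
                    seq, int(label), split,
                )
            )
    return out
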