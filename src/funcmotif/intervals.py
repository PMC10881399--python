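"""Genomic coordinate primitives shared by every stage of the pipeline.

All coordinates are 0-based, half-open (BED convention). Strand is ``"+"``,
``"-"``, or ``None`` for unstranded features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (case-preserving, N-safe)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakRecord:
    """A called peak plus its histone-mark tag count.

    ``tag_count`` is the number of H3K27ac-style tags attributed to the peak
    (in the source data, counted in an expanded window around the peak); it
    drives the active-enhancer labelling threshold downstream.
    """

    interval: GenomicInterval
    peak_id: str
    tag_count: int

    def __post_init__(self) -> None:
        if self.tag_count < 0:
            raise ValueError(f"negative tag_count for {self.peak_id}")
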