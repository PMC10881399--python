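"""Combine PWM matches with top-importance positions into functional motif calls.

A motif match (which already passed its FPR-calibrated score cutoff) is
called *functional* when at least ``min_overlap`` (default 3) of its
footprint positions fall inside the per-sequence top-importance position
set. The overlap is counted in forward coordinates regardless of match
strand — the aggregated importance track is strand-symmetric by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .attribution import TopPositionSet
from .intervals import GenomicInterval
from .motifs import MotifMatch
from .synthetic import PlantedMotifTruth

DEFAULT_MIN_OVERLAP = 3


class PairingError(KeyError):
    """Raised when a match has no importance track for its window."""


@dataclass(frozen=True)
class FunctionalMotifCall:
    match: MotifMatch
    overlap_count: int
    functional: bool
    sequence_id: str = ""


def overlap_with_top_set(match: MotifMatch, top: TopPositionSet) -> int:
    """Number of match footprint positions inside the top-importance set.

    ``top.positions`` are window-local indices when ``top.interval`` is
    set; the match interval must lie within that window.
    """
    if top.interval is not None:
        win = top.interval
        if (
            match.interval.chrom != win.chrom
            or match.interval.start < win.start
            or match.interval.end > win.end
        ):
            raise ValueError(
                f"match {match.interval} outside window {win}"
            )
        offset = win.start
    else:
        offset = 0
    footprint = range(match.interval.start - offset, match.interval.end - offset)
    top_set = set(top.positions)
    return sum(1 for p in footprint if p in top_set)


def call_functional(
    matches_by_sequence: Mapping[str, Sequence[MotifMatch]],
    top_sets: Mapping[str, TopPositionSet],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> Tuple[List[FunctionalMotifCall], Dict[str, Dict[str, int]]]:
    """Emit one call per match plus per-motif summary counts.

    ``matches_by_sequence`` and ``top_sets`` are keyed by sequence/window id;
    every key with matches must have a top set. Returns the calls sorted by
    coordinate and a summary ``{motif_id: {"n_matches": .., "n_functional": ..}}``.
    """
    calls: List[FunctionalMotifCall] = []
    summary: Dict[str, Dict[str, int]] = {}
    for seq_id in sorted(matches_by_sequence):
        matches = matches_by_sequence[seq_id]
        if not matches:
            continue
        if seq_id not in top_sets:
            raise PairingError(f"no top-position set for sequence {seq_id!r}")
        top = top_sets[seq_id]
        for match in matches:
            count = overlap_with_top_set(match, top)
            functional = count >= min_overlap
            calls.append(
                FunctionalMotifCall(match, count, functional, seq_id)
            )
            s = summary.setdefault(
                match.motif_id, {"n_matches": 0, "n_functional": 0}
            )
            s["n_matches"] += 1
            s["n_functional"] += int(functional)
    calls.sort(
        key=lambda c: (c.match.interval.chrom, c.match.interval.start,
                       c.match.strand)
    )
    return calls, summary


@dataclass(frozen=True)
class RecoveryMetrics:
    motif_id: str
    n_truth: int
    n_calls: int
    n_true_positive: int
    precision: float
    recall: float
    f1: float
    undefined_precision: bool = False


def _overlaps_within(
    a: GenomicInterval, b: GenomicInterval, tolerance_bp: int
) -> bool:
    return (
        a.chrom == b.chrom
        and a.start < b.end + tolerance_bp
        and b.start < a.end + tolerance_bp
    )


def _metrics(motif_id, truth, calls, tolerance_bp) -> RecoveryMetrics:
    tp_calls = 0
    for c in calls:
        if any(
            t.motif_id == c.match.motif_id
            and _overlaps_within(c.match.interval, t.interval, tolerance_bp)
            for t in truth
        ):
            tp_calls += 1
    recovered = 0
    for t in truth:
        if any(
            c.match.motif_id == t.motif_id
            and _overlaps_within(c.match.interval, t.interval, tolerance_bp)
            for c in calls
        ):
            recovered += 1
    undefined = len(calls) == 0
    precision = 0.0 if undefined else tp_calls / len(calls)
    recall = recovered / len(truth) if truth else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return RecoveryMetrics(
        motif_id=motif_id, n_truth=len(truth), n_calls=len(calls),
        n_true_positive=tp_calls, precision=precision, recall=recall,
        f1=f1, undefined_precision=undefined,
    )


def recovery_report(
    calls: Sequence[FunctionalMotifCall],
    truth: Sequence[PlantedMotifTruth],
    tolerance_bp: int = 0,
) -> Dict[str, RecoveryMetrics]:
    """Precision/recall/F1 of functional calls against planted truth.

    A functional call is a true positive iff a truth interval of the same
    motif id overlaps it within ``tolerance_bp``; recall counts truth
    entries hit by at least one functional call. Per-motif metrics plus a
    ``"pooled"`` entry. Empty call sets report precision 0 with the
    ``undefined_precision`` flag set.
    """
    functional = [c for c in calls if c.functional]
    motif_ids = sorted(
        {t.motif_id for t in truth} | {c.match.motif_id for c in functional}
    )
    report = {}
    for mid in motif_ids:
        report[mid] = _metrics(
            mid,
            [t for t in truth if t.motif_id == mid],
            [c for c in functional if c.match.motif_id == mid],
            tolerance_bp,
        )
    report["pooled"] = _metrics("pooled", list(truth), functional, tolerance_bp)
    return report


def write_calls(calls: Sequence[FunctionalMotifCall], path) -> None:
    """BED6+3: score = log-odds x100 rounded; extra pwm_score, overlap, flag."""
    with open(path, "w") as fh:
        for c in calls:
            iv = c.match.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.match.motif_id}"
                f"\t{round(c.match.score * 100)}\t{c.match.strand}"
                f"\t{c.match.score:.6f}\t{c.overlap_count}"
                f"\t{int(c.functional)}\n"
            )
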