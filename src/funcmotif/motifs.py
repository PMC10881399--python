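"""Position-weight-matrix scanning with empirical false-positive-rate calibration.

A :class:`PWMModel` wraps a JASPAR count matrix as per-position base
frequencies (after pseudocount regularisation) and the derived log\\ :sub:`2`
odds matrix against a background composition (uniform by default):

    log_odds[i, b] = log2(freq[i, b] / background[b])

A window of the motif's width scores as the sum of log-odds at its observed
bases; the minus-strand score of a window is the plus-strand score of its
reverse complement. The score cutoff is not analytic: it is calibrated so
that the fraction of *background windows* (regulatory-element-sized, both
strands scanned) containing at least one hit at or above the cutoff stays
below a target false-positive rate (default 0.2%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .intervals import GenomicInterval, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: fraction of each column's total count added per cell before normalisation
DEFAULT_PSEUDOCOUNT_FRACTION = 0.01
DEFAULT_TARGET_FPR = 0.002


class MotifParseError(ValueError):
    """Raised when a JASPAR matrix file cannot be parsed."""


class CalibrationError(ValueError):
    """Raised when the background set is too small for FPR calibration."""


@dataclass
class PWMModel:
    """A motif's frequency matrix, background, and derived log-odds matrix."""

    motif_id: str
    counts: np.ndarray  # W x 4, raw counts or frequencies
    pseudocount_fraction: float = DEFAULT_PSEUDOCOUNT_FRACTION
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = ""

    freq: np.ndarray = field(init=False)  # W x 4, rows sum to 1
    log_odds: np.ndarray = field(init=False)  # W x 4, log2
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise MotifParseError(
                f"{self.motif_id}: matrix must be W x 4, got {counts.shape}"
            )
        if (counts < 0).any():
            raise MotifParseError(f"{self.motif_id}: negative counts")
        totals = counts.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise MotifParseError(f"{self.motif_id}: empty matrix column")
        background = np.asarray(self.background, dtype=float)
        if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
            raise ValueError("background must be a 4-vector summing to 1")
        self.counts = counts
        self.background = background
        pseudo = self.pseudocount_fraction * totals
        regularised = counts + pseudo / 4.0
        self.freq = regularised / regularised.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(self.freq / background)

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freq.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


def load_jaspar(
    path_or_handle,
    pseudocount_fraction: float = DEFAULT_PSEUDOCOUNT_FRACTION,
    background: Optional[Sequence[float]] = None,
) -> List[PWMModel]:
    """Parse a JASPAR-format text file into :class:`PWMModel` objects.

    Accepts the modern JASPAR text layout (``>ID NAME`` header followed by
    four ``A [ ... ]``-style rows). Background defaults to uniform.
    """
    if hasattr(path_or_handle, "read"):
        handle = path_or_handle
        close = False
    else:
        handle = open(path_or_handle)
        close = True
    try:
        parsed = bio_motifs.parse(handle, "jaspar")
    except Exception as exc:  # Bio raises bare ValueError/KeyError on bad input
        raise MotifParseError(f"malformed JASPAR input: {exc}") from exc
    finally:
        if close:
            handle.close()
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    models = []
    for m in parsed:
        counts = np.column_stack([np.asarray(m.counts[b], float) for b in BASES])
        models.append(
            PWMModel(
                motif_id=m.matrix_id or m.name,
                counts=counts,
                pseudocount_fraction=pseudocount_fraction,
                background=bg,
                name=m.name or "",
            )
        )
    return models


def write_jaspar(pwms: Iterable[PWMModel], path) -> None:
    """Write count matrices back out in JASPAR text format."""
    records = []
    for p in pwms:
        counts = {b: list(p.counts[:, i]) for i, b in enumerate(BASES)}
        m = bio_motifs.Motif(alphabet="GATC", counts=counts)
        m.matrix_id = p.motif_id
        m.name = p.name or p.motif_id
        records.append(m)
    text = bio_motifs.write(records, "jaspar")
    with open(path, "w") as fh:
        fh.write(text)


def encode_indices(sequence: str) -> np.ndarray:
    """Map ACGT to 0..3; any other base (e.g. N) to -1."""
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def score_window(pwm: PWMModel, window: str) -> float:
    """Log-odds score of a single window of exactly the motif's width."""
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != motif width {pwm.width}"
        )
    idx = encode_indices(window)
    if (idx < 0).any():
        raise ValueError("window contains non-ACGT bases; score undefined")
    return float(pwm.log_odds[np.arange(pwm.width), idx].sum())


def _sliding_scores(pwm: PWMModel, idx: np.ndarray) -> np.ndarray:
    """Plus-strand scores at every offset; NaN where the window contains N."""
    w = pwm.width
    n = idx.size - w + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n, np.nan)
    if valid.any():
        v = windows[valid]
        scores[valid] = pwm.log_odds[np.arange(w), v].sum(axis=1)
    return scores


def best_window_score(pwm: PWMModel, sequence: str) -> float:
    """Best log-odds score over all offsets and both strands.

    Used for calibration (a background window is a false positive if *any*
    offset on *either* strand passes). Returns ``-inf`` when no valid
    (N-free) window exists.
    """
    fwd = _sliding_scores(pwm, encode_indices(sequence))
    rev = _sliding_scores(pwm, encode_indices(reverse_complement(sequence)))
    both = np.concatenate([fwd, rev])
    both = both[~np.isnan(both)]
    return float(both.max()) if both.size else float("-inf")


@dataclass(frozen=True)
class CutoffCalibration:
    """Result of empirically calibrating a PWM score cutoff to a target FPR."""

    motif_id: str
    target_fpr: float
    cutoff: float
    n_background_windows: int
    achieved_fpr: float
    background_source: str = "unspecified"
    seed: Optional[int] = None


def calibrate_cutoff(
    pwm: PWMModel,
    background_windows: Iterable[str],
    target_fpr: float = DEFAULT_TARGET_FPR,
    seed: Optional[int] = None,
    background_source: str = "unspecified",
) -> CutoffCalibration:
    """Find the minimum score cutoff with empirical FPR below ``target_fpr``.

    Every background window is scored at every offset on both strands; its
    summary statistic is its best score. The cutoff is the smallest value on
    the grid of observed best scores for which the fraction of windows at or
    above it is strictly below ``target_fpr``. ``target_fpr >= 1`` is a
    vacuous bound and returns the minimum observed score.
    """
    best = np.array([best_window_score(pwm, w) for w in background_windows])
    n = best.size
    if target_fpr <= 0:
        raise ValueError("target_fpr must be positive")
    minimum = int(np.ceil(10.0 / target_fpr)) if target_fpr < 1.0 else 1
    if n < minimum:
        raise CalibrationError(
            f"need >= {minimum} background windows for target_fpr="
            f"{target_fpr}, got {n}"
        )
    grid = np.unique(best)  # ascending
    if target_fpr >= 1.0:
        cutoff = float(grid[0])
        achieved = 1.0
    else:
        # fraction passing at cutoff g: count(best >= g) / n, non-increasing in g
        passing = n - np.searchsorted(np.sort(best), grid, side="left")
        fpr = passing / n
        ok = np.nonzero(fpr < target_fpr)[0]
        if ok.size == 0:
            # even the strictest observed score passes too often; one tick above
            cutoff = float(np.nextafter(grid[-1], np.inf))
            achieved = 0.0
        else:
            cutoff = float(grid[ok[0]])
            achieved = float(fpr[ok[0]])
    return CutoffCalibration(
        motif_id=pwm.motif_id,
        target_fpr=target_fpr,
        cutoff=cutoff,
        n_background_windows=n,
        achieved_fpr=achieved,
        background_source=background_source,
        seed=seed,
    )


@dataclass(frozen=True)
class MotifMatch:
    """A PWM hit in forward-strand coordinates."""

    interval: GenomicInterval
    strand: str
    score: float
    motif_id: str


def scan(
    pwm: PWMModel,
    sequence: str,
    cutoff: float,
    chrom: str = "seq",
    offset: int = 0,
) -> List[MotifMatch]:
    """Report every width-W window scoring ``>= cutoff`` on either strand.

    Coordinates are forward-strand (``offset`` shifts them into genome
    space when ``sequence`` is a window of a chromosome). Output is sorted
    by start, then strand (``+`` before ``-``). Overlapping matches are all
    reported.
    """
    w = pwm.width
    if len(sequence) < w:
        return []
    idx = encode_indices(sequence)
    fwd = _sliding_scores(pwm, idx)
    rev_raw = _sliding_scores(pwm, encode_indices(reverse_complement(sequence)))
    # offset j on the reverse complement covers forward positions
    # [L - w - j, L - j); re-align by index reversal
    rev = rev_raw[::-1]
    matches = []
    for i in range(fwd.size):
        for strand, s in (("+", fwd[i]), ("-", rev[i])):
            if not np.isnan(s) and s >= cutoff:
                matches.append(
                    MotifMatch(
                        interval=GenomicInterval(
                            chrom, offset + i, offset + i + w, strand
                        ),
                        strand=strand,
                        score=float(s),
                        motif_id=pwm.motif_id,
                    )
                )
    matches.sort(key=lambda m: (m.interval.start, m.strand))
    return matches
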