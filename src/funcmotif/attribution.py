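"""Per-nucleotide importance scores and top-fraction position selection.

Importance is computed against a uniform nucleotide background — a reference
input of 0.25 per base at every position — with one of two back-ends:

* ``deeplift-rescale`` (default): DeepLIFT with the rescale rule for
  elementwise nonlinearities and the linear rule for affine layers; its
  contributions satisfy summation-to-delta, i.e. they sum to
  ``model(x) - model(reference)`` on the probability scale.
* ``grad_x_input``: gradient of the output probability times the input
  difference from the reference; no summation-to-delta guarantee.

Per-base contributions collapse to one signed score per position by
summing over the four base channels, which preserves summation-to-delta. Strand handling follows the interpretation-time convention:
score the window and its reverse complement separately, re-align the
reverse scores by index reversal, and take the absolute maximum at each
aligned position. The per-sequence "predicted functional nucleotides" are
the top 20% (for a 300 bp window, the top 60) positions of that final track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .classifier import TrainedClassifier
from .dataset import encode_onehot
from .intervals import GenomicInterval, reverse_complement
from .nn import sigmoid

DEFAULT_TOP_FRACTION = 0.2
METHODS = ("deeplift-rescale", "grad_x_input")


class AttributionError(RuntimeError):
    pass


@dataclass(frozen=True)
class ImportanceTrack:
    scores: np.ndarray  # length L, non-negative after strand aggregation
    method: str
    reference: str = "uniform"
    interval: Optional[GenomicInterval] = None


@dataclass(frozen=True)
class TopPositionSet:
    positions: Tuple[int, ...]  # ascending coordinate order
    fraction: float
    k: int
    interval: Optional[GenomicInterval] = None


def _collapse_positionwise(contributions: np.ndarray) -> np.ndarray:
    # one signed score per position: the sum of contributions over the four
    # base channels. With a uniform reference the off channels carry real
    # (negative) contribution mass, so only the channel sum preserves
    # summation-to-delta; N rows (all 0.25, equal to the reference) get 0
    return contributions.sum(axis=1)


def importance_scores(
    model: TrainedClassifier,
    sequence: str,
    method: str = "deeplift-rescale",
) -> np.ndarray:
    """Signed per-position importance of ``sequence`` in forward orientation."""
    if method not in METHODS:
        raise AttributionError(
            f"unknown method {method!r}; choose from {METHODS}"
        )
    L = model.config.window_length
    if len(sequence) != L:
        raise AttributionError(f"sequence length {len(sequence)} != {L}")
    x = encode_onehot(sequence)[None, :, :]
    network = model.network
    logit, caches = network.forward(x, with_caches=True)

    if method == "deeplift-rescale":
        ref = np.full_like(x, 0.25)
        ref_logit, ref_caches = network.forward(ref, with_caches=True)
        dz = logit - ref_logit
        # rescale through the output sigmoid so contributions live on the
        # probability scale the model reports
        m_logit = np.where(
            np.abs(dz) > 1e-9,
            (sigmoid(logit) - sigmoid(ref_logit)) / np.where(
                np.abs(dz) > 1e-9, dz, 1.0
            ),
            sigmoid(logit) * (1.0 - sigmoid(logit)),
        )
        multipliers = network.deeplift_multipliers(m_logit, caches, ref_caches)
        contributions = multipliers[0] * (x[0] - ref[0])
    else:
        dprob = sigmoid(logit) * (1.0 - sigmoid(logit))
        grads = _input_gradient(network, dprob, caches)
        contributions = grads[0] * (x[0] - 0.25)
    return _collapse_positionwise(contributions)


def _input_gradient(network, dlogit, caches) -> np.ndarray:
    d = dlogit[:, None]
    for i in range(len(network.layers) - 1, -1, -1):
        d, _ = network.layers[i].backward(d, caches[i])
    return d


def aggregate_strands(
    forward_scores: np.ndarray, reverse_scores_aligned: np.ndarray
) -> np.ndarray:
    """Absolute maximum of the two strand score tracks at each position.

    ``reverse_scores_aligned`` must already be re-aligned to forward
    coordinates (index-reversed from the reverse-complement run). The
    operation is commutative, so which strand is "original" is immaterial.
    """
    f = np.asarray(forward_scores, dtype=float)
    r = np.asarray(reverse_scores_aligned, dtype=float)
    if f.shape != r.shape:
        raise ValueError(f"shape mismatch {f.shape} vs {r.shape}")
    return np.maximum(np.abs(f), np.abs(r))


def attribute_window(
    model: TrainedClassifier,
    sequence: str,
    method: str = "deeplift-rescale",
    interval: Optional[GenomicInterval] = None,
) -> ImportanceTrack:
    """Full strand-aggregated importance track for one window."""
    fwd = importance_scores(model, sequence, method)
    rev = importance_scores(model, reverse_complement(sequence), method)
    final = aggregate_strands(fwd, rev[::-1])
    return ImportanceTrack(
        scores=final, method=method, reference="uniform", interval=interval
    )


def top_fraction_positions(
    final_scores: np.ndarray,
    fraction: float = DEFAULT_TOP_FRACTION,
    interval: Optional[GenomicInterval] = None,
) -> TopPositionSet:
    """The k = floor(fraction * L) highest-scoring positions.

    Ties at the k-th value resolve to the larger score first, then the
    smaller coordinate; positions are returned in ascending order.
    """
    scores = np.asarray(final_scores, dtype=float)
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1]: {fraction}")
    L = scores.size
    k = int(np.floor(fraction * L))
    if k == 0:
        raise ValueError(f"fraction {fraction} selects zero of {L} positions")
    order = np.lexsort((np.arange(L), -scores))  # score desc, coordinate asc
    chosen = np.sort(order[:k])
    return TopPositionSet(
        positions=tuple(int(p) for p in chosen),
        fraction=fraction, k=k, interval=interval,
    )


def write_track(
    track: ImportanceTrack, top: TopPositionSet, path
) -> None:
    """4-column TSV: chrom, pos (genome coordinates when known), score, flag."""
    chrom = track.interval.chrom if track.interval else "seq"
    offset = track.interval.start if track.interval else 0
    top_set = set(top.positions)
    with open(path, "w") as fh:
        for i, s in enumerate(track.scores):
            fh.write(
                f"{chrom}\t{offset + i}\t{s:.6g}\t{int(i in top_set)}\n"
            )
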