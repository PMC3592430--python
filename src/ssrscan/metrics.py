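"""Evaluation measures for microsatellite detection.

All measures are computed on merged interval sets, so how a tool happens to
split or order its calls never changes the base-pair totals.

* sensitivity(a, b): percent of the bp found by tool b that tool a also
  covers, ``100 * O_ab / L_b``.
* fpr: bp of detections per Mbp of a zero-order shuffled sequence,
  ``1e6 * L_a / S`` (optionally excluding detections inside known
  repetitive or low-complexity intervals of the shuffled sequence).
* precision (modified): ``100 * O_ref,a / (O_ref,a + L_a_on_shuffled)`` —
  true positives are detections overlapping the reference annotation, and
  false positives are detections made in the shuffled sequence of the same
  length.
* percentage predicted (PP): percent of the chromosome called MS,
  ``100 * L_a / T``.

``S`` and ``T`` are whole-sequence lengths, N runs included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import Interval, merge_intervals, total_length


@dataclass
class EvalResult:
    """One evaluation: the four measures plus the raw bp quantities."""

    sensitivity: float  # percent
    fpr: float  # bp per Mbp of shuffled sequence
    precision: float  # percent
    pp: float  # percent of the chromosome called MS
    overlap_bp: int
    detected_bp: int
    reference_bp: int
    shuffled_detected_bp: int
    sequence_length: int


def overlap_length(a: Iterable[Interval], b: Iterable[Interval]) -> int:
    """Total bp in the intersection of two interval sets (merged first)."""
    am, bm = merge_intervals(a), merge_intervals(b)
    total = 0
    i = j = 0
    while i < len(am) and j < len(bm):
        x, y = am[i], bm[j]
        if x.seq_id != y.seq_id:
            if x.seq_id < y.seq_id:
                i += 1
            else:
                j += 1
            continue
        lo = max(x.start, y.start)
        hi = min(x.end, y.end)
        if hi > lo:
            total += hi - lo
        if x.end <= y.end:
            i += 1
        else:
            j += 1
    return total


def sensitivity(a: Iterable[Interval], b: Iterable[Interval]) -> float:
    """Percent of tool b's bp also found by tool a."""
    lb = total_length(b)
    if lb == 0:
        raise ValueError("sensitivity is undefined: reference set covers 0 bp")
    return 100.0 * overlap_length(a, b) / lb


def _excluded_bp(detections: Iterable[Interval], exclusions: Iterable[Interval] | None) -> int:
    if exclusions is None:
        return 0
    return overlap_length(detections, exclusions)


def fpr(
    detections_on_shuffled: Iterable[Interval],
    shuffled_length: int,
    exclusions: Iterable[Interval] | None = None,
) -> float:
    """Detected bp per Mbp of shuffled sequence."""
    if shuffled_length <= 0:
        raise ValueError("shuffled sequence length must be positive")
    dets = merge_intervals(detections_on_shuffled)
    la = total_length(dets) - _excluded_bp(dets, exclusions)
    return 1e6 * la / shuffled_length


def precision(
    a_on_real: Iterable[Interval],
    reference: Iterable[Interval],
    a_on_shuffled: Iterable[Interval],
    exclusions: Iterable[Interval] | None = None,
) -> float:
    """Modified precision: reference overlap over itself plus shuffled detections."""
    o = overlap_length(a_on_real, reference)
    shuf = merge_intervals(a_on_shuffled)
    la_shuffled = total_length(shuf) - _excluded_bp(shuf, exclusions)
    denom = o + la_shuffled
    if denom == 0:
        raise ValueError(
            "precision is undefined: no reference overlap and no shuffled detections"
        )
    return 100.0 * o / denom


def percentage_predicted(a: Iterable[Interval], sequence_length: int) -> float:
    """Percent of the scanned chromosome predicted as MS."""
    if sequence_length <= 0:
        raise ValueError("sequence length must be positive")
    return 100.0 * total_length(a) / sequence_length


def evaluate(
    detections: Sequence[Interval],
    reference: Sequence[Interval],
    shuffled_detections: Sequence[Interval],
    sequence_length: int,
    exclusions: Sequence[Interval] | None = None,
) -> EvalResult:
    """Convenience bundle of all four measures for one detection run."""
    dets = merge_intervals(detections)
    ref = merge_intervals(reference)
    shuf = merge_intervals(shuffled_detections)
    o = overlap_length(dets, ref)
    la_shuf = total_length(shuf) - _excluded_bp(shuf, exclusions)
    denom = o + la_shuf
    return EvalResult(
        sensitivity=100.0 * o / total_length(ref) if ref else float("nan"),
        fpr=1e6 * la_shuf / sequence_length,
        precision=100.0 * o / denom if denom else float("nan"),
        pp=100.0 * total_length(dets) / sequence_length,
        overlap_bp=o,
        detected_bp=total_length(dets),
        reference_bp=total_length(ref),
        shuffled_detected_bp=la_shuf,
        sequence_length=sequence_length,
    )
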