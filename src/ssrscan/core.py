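"""Core value types shared across the package.

Coordinates are 0-based half-open everywhere in memory; only the
tab-separated interval report on disk uses 1-based inclusive positions
(see :mod:`ssrscan.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}.

    Sequences are normalized to upper case on construction through
    :func:`ssrscan.io_formats.read_fasta`; the constructor itself does not
    re-validate the alphabet so that hot paths stay cheap.
    """

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open genomic interval ``[start, end)`` on a named sequence.

    ``score`` optionally carries the logistic value assigned by the filter.
    """

    seq_id: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort intervals and merge overlapping or touching ones per sequence.

    Scores are dropped on merge; the result is the canonical form used for
    base-pair bookkeeping in :mod:`ssrscan.metrics`.
    """
    by_key = sorted(intervals, key=lambda iv: (iv.seq_id, iv.start, iv.end))
    merged: list[Interval] = []
    for iv in by_key:
        if merged and merged[-1].seq_id == iv.seq_id and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.seq_id, last.start, iv.end)
        else:
            merged.append(Interval(iv.seq_id, iv.start, iv.end))
    return merged


def total_length(intervals: Iterable[Interval]) -> int:
    """Total bp covered by a set of intervals, after merging."""
    return sum(len(iv) for iv in merge_intervals(intervals))
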