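"""Word-identity scoring: turn a nucleotide sequence into a score series.

Every position ``i`` is treated as the start of a word of length ``n``.
That word is aligned, without gaps, against every word of the same length
that lies fully inside the two flanking windows: the ``m`` positions
immediately preceding ``i`` and the ``m`` positions immediately following
the end of the query word (the query never overlaps a candidate, so a
trivial self-match is impossible).  The score of position ``i`` is the best
per-position match count over all those candidates, an integer in
``[0, n]``.  Inside a tandem repeat the flanks contain near-exact copies of
the query word, so scores saturate at ``n``; background positions rarely
exceed chance agreement.

The transform runs in O(m * h) for a sequence of length h: one vectorized
pass per candidate offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Interval, SequenceRecord

_N_BYTE = ord("N")


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the scoring transform.

    word_length
        Length n of the compared words, in bp.  Default 6: the longest
        microsatellite motif, and short motifs tile into 6-bp words (three
        AT copies form the repeated word ATATAT).
    half_window
        Length m of each flanking window, in bp.  Default 24; larger
        windows raise background scores without improving repeat scores.
    """

    word_length: int = 6
    half_window: int = 24

    def __post_init__(self) -> None:
        if self.word_length < 1:
            raise ValueError("word_length must be >= 1")
        if self.half_window < self.word_length:
            raise ValueError(
                "half_window must be >= word_length so a flank can hold a full word"
            )


@dataclass
class ScoreSeries:
    """Per-nucleotide integer scores in [0, word_length] for one sequence."""

    seq_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int16)

    def __len__(self) -> int:
        return len(self.scores)


def identity_score(x: str, y: str) -> int:
    """Gapless identity score of two equal-length words.

    Counts positions where the two words carry the same base; 'N' matches
    nothing, including another 'N'.
    """
    if len(x) != len(y):
        raise ValueError(f"words differ in length: {len(x)} vs {len(y)}")
    return sum(a == b and a != "N" for a, b in zip(x, y))


def score_sequence(record: SequenceRecord, params: ScoringParams = ScoringParams()) -> ScoreSeries:
    """Compute the score series of a sequence.

    Windows are truncated at the sequence boundaries.  Positions whose
    query word would run past the end of the sequence, or whose query word
    contains an N, score 0.  Candidate flank words containing an N are
    skipped.
    """
    n = params.word_length
    m = params.half_window
    code = np.frombuffer(record.seq.encode("ascii"), dtype=np.uint8)
    h = len(code)
    best = np.zeros(h, dtype=np.int16)
    if h < 2 * n:  # no position can see a non-overlapping candidate word
        return ScoreSeries(record.id, best)

    is_n = code == _N_BYTE
    ncum = np.concatenate(([0], np.cumsum(is_n)))
    # word_has_n[p] is True when the word starting at p contains an N
    word_has_n = (ncum[n:] - ncum[:-n]) > 0  # length h - n + 1

    # A candidate in the right window starts at i + e with e in [n, m]; by
    # symmetry the same shifted-match array serves the left window (the
    # candidate at i - e of query i is the query at i - e matched rightward).
    for e in range(n, m + 1):
        if h - e < n:
            break
        eq = (code[:-e] == code[e:]) & ~is_n[:-e] & ~is_n[e:]
        c = np.concatenate(([0], np.cumsum(eq)))
        ws = (c[n:] - c[:-n]).astype(np.int16)  # ws[p] = matches(word p, word p+e)
        k = len(ws)  # = h - e - n + 1
        # right flank of query i = p: candidate word at p + e
        ok = ~word_has_n[e : e + k]
        np.maximum(best[:k], np.where(ok, ws, 0), out=best[:k])
        # left flank of query i = p + e: candidate word at p
        ok = ~word_has_n[:k]
        np.maximum(best[e : e + k], np.where(ok, ws, 0), out=best[e : e + k])

    # positions without a full query word, or whose query word contains N
    best[h - n + 1 :] = 0
    head = best[: h - n + 1]
    head[word_has_n] = 0
    return ScoreSeries(record.id, best)


def score_statistics(series: ScoreSeries, interval: Interval) -> tuple[int, float]:
    """Length and average score of a detection on its score series."""
    if interval.end > len(series):
        raise ValueError(
            f"interval [{interval.start}, {interval.end}) exceeds series length {len(series)}"
        )
    chunk = series.scores[interval.start : interval.end]
    if chunk.size == 0:
        raise ValueError("empty interval has no score statistics")
    return int(chunk.size), float(chunk.mean())
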