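"""Independent reference implementations used as test oracles.

These deliberately favour clarity over speed and share no code with the
package paths they check.
"""

from __future__ import annotations

import itertools
import math


def brute_force_scores(seq: str, n: int, m: int) -> list[int]:
    """Quadratic per-position best-identity scoring, straight from the rules."""
    h = len(seq)
    out = [0] * h
    for i in range(h):
        if i + n > h or "N" in seq[i : i + n]:
            continue
        query = seq[i : i + n]
        candidates = list(range(max(0, i - m), i - n + 1)) + list(
            range(i + n, min(h, i + n + m) - n + 1)
        )
        best = 0
        for j in candidates:
            word = seq[j : j + n]
            if "N" in word:
                continue
            best = max(best, sum(a == b != "N" for a, b in zip(query, word)))
        out[i] = best
    return out


def brute_force_comparisons(seq_length: int, n: int, m: int) -> int:
    """Number of word-vs-word comparisons the scoring transform performs."""
    total = 0
    h = seq_length
    for i in range(h):
        if i + n > h:
            continue
        total += len(range(max(0, i - m), i - n + 1))
        total += len(range(i + n, min(h, i + n + m) - n + 1))
    return total


def enumerate_best_path(scores, priors, transitions, emissions) -> tuple[float, tuple]:
    """Best joint log probability over all 2^L state paths, by enumeration."""
    best = -math.inf
    best_path = ()
    length = len(scores)
    for path in itertools.product((0, 1), repeat=length):
        lp = _safe_log(priors[path[0]]) + _safe_log(emissions[path[0]][scores[0]])
        for t in range(1, length):
            lp += _safe_log(transitions[path[t - 1]][path[t]])
            lp += _safe_log(emissions[path[t]][scores[t]])
        if lp > best:
            best = lp
            best_path = path
    return best, best_path


def _safe_log(p: float) -> float:
    return math.log(p) if p > 0 else -math.inf
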