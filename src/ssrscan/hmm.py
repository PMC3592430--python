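"""Two-state hidden Markov model over score series.

State 0 (non-MS) emits the low scores typical of background sequence;
state 1 (MS) emits the high scores produced inside tandem repeats.  The
model is trained supervised, from score series paired with per-position
state labels, and decoded with the Viterbi algorithm in log space.

Training counts follow the usual relative-frequency estimates with add-one
(Laplace) smoothing on every count table, so no emission is ever exactly
zero.  Priors are estimated from the states observed at the starts of
fixed-length training segments (default 500 bp); transition bigrams are not
counted across segment joins.  Decoding always runs on the whole,
unsegmented series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import Interval
from .scoring import ScoreSeries

NONMS, MS = 0, 1
_ROW_TOL = 1e-9

StatePath = np.ndarray  # uint8 array over {NONMS, MS}, one label per score


@dataclass
class TwoStateHMM:
    """Priors, 2x2 transitions and 2x(n+1) emissions over scores 0..n."""

    priors: np.ndarray
    transitions: np.ndarray
    emissions: np.ndarray

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)

    @property
    def n(self) -> int:
        """Word length the emissions are defined over (scores 0..n)."""
        return self.emissions.shape[1] - 1

    def validate(self) -> None:
        if self.priors.shape != (2,) or self.transitions.shape != (2, 2):
            raise ValueError("model must have 2 states")
        if self.emissions.ndim != 2 or self.emissions.shape[0] != 2:
            raise ValueError("emissions must be a 2 x (n+1) matrix")
        for name, block in (
            ("priors", self.priors[None, :]),
            ("transitions", self.transitions),
            ("emissions", self.emissions),
        ):
            if np.any(block < 0):
                raise ValueError(f"{name} contain a negative probability")
            sums = block.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > _ROW_TOL):
                raise ValueError(f"{name} rows must sum to 1 (got {sums})")

    def sample(self, length: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw (scores, states) of the given length from the model."""
        u_state = rng.random(length)
        scores = np.empty(length, dtype=np.int16)
        states = np.empty(length, dtype=np.uint8)
        emis_cum = np.cumsum(self.emissions, axis=1)
        u_emit = rng.random(length)
        stay0 = self.transitions[0, 0]
        stay1 = self.transitions[1, 1]
        s = 0 if u_state[0] < self.priors[0] else 1
        for t in range(length):
            if t:
                stay = stay0 if s == 0 else stay1
                if u_state[t] >= stay:
                    s = 1 - s
            states[t] = s
            scores[t] = np.searchsorted(emis_cum[s], u_emit[t], side="right")
        return scores, states


def train_supervised(
    data: Iterable[tuple[ScoreSeries, Sequence[int]]],
    segment_length: int = 500,
    n: int = 6,
    require_both_states: bool = True,
) -> TwoStateHMM:
    """Estimate a TwoStateHMM from labeled score series.

    Each series is cut into non-overlapping segments of ``segment_length``
    (the last, partial segment is kept).  Priors come from segment-start
    states, transitions from within-segment state bigrams, emissions from
    per-state score frequencies; all three tables get add-one smoothing.
    """
    if segment_length < 2:
        raise ValueError("segment_length must be >= 2")
    prior_counts = np.zeros(2)
    trans_counts = np.zeros((2, 2))
    emit_counts = np.zeros((2, n + 1))
    seen = False
    for series, labels in data:
        seen = True
        lab = np.asarray(labels, dtype=np.int64)
        sc = np.asarray(series.scores, dtype=np.int64)
        if lab.shape != sc.shape:
            raise ValueError(
                f"labels ({lab.shape}) and scores ({sc.shape}) differ in length "
                f"for series {series.seq_id!r}"
            )
        if sc.size == 0:
            continue
        if sc.min() < 0 or sc.max() > n:
            raise ValueError(f"scores outside [0, {n}] in series {series.seq_id!r}")
        prior_counts += np.bincount(lab[::segment_length], minlength=2)
        if sc.size > 1:
            big = np.bincount(2 * lab[:-1] + lab[1:], minlength=4).reshape(2, 2)
            # remove bigrams that straddle segment joins
            joins = np.arange(segment_length, sc.size, segment_length)
            if joins.size:
                big -= np.bincount(
                    2 * lab[joins - 1] + lab[joins], minlength=4
                ).reshape(2, 2)
            trans_counts += big
        emit_counts += np.bincount(lab * (n + 1) + sc, minlength=2 * (n + 1)).reshape(
            2, n + 1
        )
    if not seen:
        raise ValueError("no training series supplied")
    if require_both_states and emit_counts[MS].sum() == 0:
        raise ValueError(
            "no MS-labeled positions in the training data; check that the "
            "annotation intervals actually overlap the training sequence"
        )
    model = TwoStateHMM(
        priors=(prior_counts + 1) / (prior_counts.sum() + 2),
        transitions=(trans_counts + 1) / (trans_counts.sum(axis=1, keepdims=True) + 2),
        emissions=(emit_counts + 1) / (emit_counts.sum(axis=1, keepdims=True) + n + 1),
    )
    model.validate()
    return model


def viterbi(series: ScoreSeries, model: TwoStateHMM) -> StatePath:
    """Maximum-probability state path for a score series, in log space.

    Ties are broken toward the non-MS state, which makes decoding
    deterministic and conservative (fewer spurious MS calls).
    """
    obs = np.asarray(series.scores, dtype=np.int64)
    length = obs.size
    path = np.zeros(length, dtype=np.uint8)
    if length == 0:
        return path
    if obs.min() < 0 or obs.max() > model.n:
        raise ValueError(f"score outside emission support [0, {model.n}]")
    with np.errstate(divide="ignore"):
        le = np.log(model.emissions)
        lt = np.log(model.transitions)
        lp = np.log(model.priors)
    e0 = le[0][obs].tolist()
    e1 = le[1][obs].tolist()
    t00, t01 = float(lt[0, 0]), float(lt[0, 1])
    t10, t11 = float(lt[1, 0]), float(lt[1, 1])
    back = np.empty((length, 2), dtype=np.uint8)
    v0 = float(lp[0]) + e0[0]
    v1 = float(lp[1]) + e1[0]
    for t in range(1, length):
        a = v0 + t00
        b = v1 + t10
        if a >= b:  # tie -> predecessor nonMS
            nv0 = a + e0[t]
            back[t, 0] = 0
        else:
            nv0 = b + e0[t]
            back[t, 0] = 1
        a = v0 + t01
        b = v1 + t11
        if a >= b:
            nv1 = a + e1[t]
            back[t, 1] = 0
        else:
            nv1 = b + e1[t]
            back[t, 1] = 1
        v0, v1 = nv0, nv1
    s = 0 if v0 >= v1 else 1  # tie -> nonMS
    path[length - 1] = s
    for t in range(length - 1, 0, -1):
        s = back[t, s]
        path[t - 1] = s
    return path


def path_log_probability(series: ScoreSeries, path: Sequence[int], model: TwoStateHMM) -> float:
    """Joint log probability of (path, scores) under the model."""
    obs = np.asarray(series.scores, dtype=np.int64)
    lab = np.asarray(path, dtype=np.int64)
    if obs.shape != lab.shape:
        raise ValueError("path and series differ in length")
    if obs.size == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        lp = np.log(model.priors)
        lt = np.log(model.transitions)
        le = np.log(model.emissions)
    total = lp[lab[0]] + le[lab, obs].sum()
    if obs.size > 1:
        total += lt[lab[:-1], lab[1:]].sum()
    return float(total)


def extract_segments(path: StatePath, seq_id: str) -> list[Interval]:
    """Maximal runs of MS labels as half-open intervals, in order."""
    lab = np.asarray(path, dtype=np.int8)
    if lab.size == 0:
        return []
    padded = np.concatenate(([0], lab, [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [Interval(seq_id, int(s), int(e)) for s, e in zip(starts, ends)]
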