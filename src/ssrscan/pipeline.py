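"""End-to-end detection and the automated training pipeline.

Detection chains the three components: score the sequence, decode the
score series with the two-state HMM, convert MS-state runs into candidate
intervals, and keep the candidates the logistic filter accepts.

Training reproduces the supervised protocol on any annotated sequence:
split the chromosome into contiguous thirds (train / validate / test),
train the HMM on per-position labels of the training third, run the HMM on
the training third and on its zero-order shuffle, label the resulting
detections (annotation overlap => positive; shuffled => negative;
unannotated real detections are discarded, since they are not necessarily
false positives), fit the logistic filter, and evaluate all three thirds
so over-fitting is visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import Interval, SequenceRecord, merge_intervals
from .glm_filter import GlmFilter, LabeledDetection, apply_filter, train_glm
from .hmm import TwoStateHMM, extract_segments, train_supervised, viterbi
from .io_formats import ModelFile
from .metrics import EvalResult, evaluate
from .scoring import ScoreSeries, ScoringParams, score_sequence, score_statistics
from .synthetic import GenomeAnnotation

logger = logging.getLogger(__name__)


@dataclass
class DetectorConfig:
    """Knobs of the training pipeline; all randomness flows from ``seed``."""

    scoring: ScoringParams = field(default_factory=ScoringParams)
    threshold: float = 0.5
    segment_length: int = 500
    seed: int = 0


@dataclass
class TrainingSplit:
    """Three contiguous spans covering the chromosome, with their truth sets."""

    spans: tuple[Interval, Interval, Interval]
    annotations: tuple[list[Interval], list[Interval], list[Interval]]

    names = ("train", "validate", "test")


@dataclass
class SpanEvaluation:
    name: str
    result: EvalResult
    n_detections: int


@dataclass
class TrainingReport:
    spans: list[SpanEvaluation]
    n_glm_positives: int
    n_glm_negatives: int

    def sensitivities(self) -> dict[str, float]:
        return {s.name: s.result.sensitivity for s in self.spans}


def shuffle_sequence(record: SequenceRecord, seed: int | np.random.Generator) -> SequenceRecord:
    """Zero-order shuffle: permute non-N bases uniformly, leave Ns in place."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(record.seq.encode("ascii"), dtype=np.uint8).copy()
    idx = np.flatnonzero(arr != ord("N"))
    arr[idx] = arr[idx][rng.permutation(idx.size)]
    return SequenceRecord(record.id, arr.tobytes().decode("ascii"))


def build_training_split(
    record: SequenceRecord, annotation: list[Interval]
) -> TrainingSplit:
    """Cut the sequence into three near-equal contiguous spans.

    Annotation intervals are clipped at span boundaries; the piece inside
    each span stays with that span.
    """
    length = len(record)
    bounds = [0, length // 3, 2 * length // 3, length]
    spans = tuple(
        Interval(record.id, bounds[k], bounds[k + 1]) for k in range(3)
    )
    parts: tuple[list[Interval], ...] = ([], [], [])
    for iv in merge_intervals(annotation):
        if iv.seq_id != record.id or iv.end > length:
            raise ValueError(
                f"annotation interval {iv} lies outside record {record.id!r}"
            )
        for k in range(3):
            lo = max(iv.start, bounds[k])
            hi = min(iv.end, bounds[k + 1])
            if hi > lo:
                parts[k].append(Interval(record.id, lo, hi))
    return TrainingSplit(spans=spans, annotations=parts)


def _non_n_subintervals(interval: Interval, seq: str) -> list[Interval]:
    """Clip a detection to its non-N parts (dropped entirely if all N)."""
    out: list[Interval] = []
    start = None
    for pos in range(interval.start, interval.end):
        if seq[pos] == "N":
            if start is not None:
                out.append(replace(interval, start=start, end=pos))
                start = None
        elif start is None:
            start = pos
    if start is not None:
        out.append(replace(interval, start=start, end=interval.end))
    return out


def hmm_candidates(
    record: SequenceRecord, hmm: TwoStateHMM, params: ScoringParams
) -> tuple[ScoreSeries, list[tuple[Interval, int, float]]]:
    """Score + decode one record; candidates come with (length, average score)."""
    series = score_sequence(record, params)
    path = viterbi(series, hmm)
    candidates: list[tuple[Interval, int, float]] = []
    for seg in extract_segments(path, record.id):
        for piece in _non_n_subintervals(seg, record.seq):
            length, avg = score_statistics(series, piece)
            candidates.append((piece, length, avg))
    return series, candidates


def detect_record(
    record: SequenceRecord, model: ModelFile, threshold: float | None = None
) -> list[Interval]:
    """Filtered microsatellite detections for one record, with logistic values."""
    params = ScoringParams(model.word_length, model.half_window)
    _, candidates = hmm_candidates(record, model.hmm, params)
    kept = apply_filter(candidates, model.glm, threshold)
    logger.info(
        "%s: %d HMM candidates, %d kept by filter", record.id, len(candidates), len(kept)
    )
    return kept


def detect(
    records, model: ModelFile, threshold: float | None = None
) -> dict[str, list[Interval]]:
    """Run detection record by record; returns detections keyed by record id."""
    model.validate()
    return {rec.id: detect_record(rec, model, threshold) for rec in records}


def _labels_from_annotation(length: int, intervals: list[Interval], offset: int = 0) -> np.ndarray:
    labels = np.zeros(length, dtype=np.uint8)
    for iv in intervals:
        labels[iv.start - offset : iv.end - offset] = 1
    return labels


def train_full(
    record: SequenceRecord,
    annotation: GenomeAnnotation | list[Interval],
    config: DetectorConfig = DetectorConfig(),
) -> tuple[ModelFile, TrainingReport]:
    """Train HMM + logistic filter on an annotated sequence; evaluate all thirds."""
    intervals = annotation.intervals if isinstance(annotation, GenomeAnnotation) else list(annotation)
    if not intervals:
        raise ValueError("training requires a non-empty annotation")
    rng = np.random.default_rng(config.seed)
    shuffle_seeds = rng.integers(2**31, size=3)

    split = build_training_split(record, intervals)
    train_span = split.spans[0]
    train_seq = SequenceRecord(record.id, record.seq[train_span.start : train_span.end])
    train_truth_local = [
        replace(iv, start=iv.start - train_span.start, end=iv.end - train_span.start)
        for iv in split.annotations[0]
    ]

    series = score_sequence(train_seq, config.scoring)
    labels = _labels_from_annotation(len(train_seq), train_truth_local)
    hmm = train_supervised(
        [(series, labels)],
        segment_length=config.segment_length,
        n=config.scoring.word_length,
    )

    # Label HMM candidates: real-sequence detections overlapping the truth by
    # >= 1 bp are positives; detections on the shuffled training third are
    # negatives; unannotated real detections are discarded.
    _, real_candidates = hmm_candidates(train_seq, hmm, config.scoring)
    shuffled_train = shuffle_sequence(train_seq, int(shuffle_seeds[0]))
    _, shuf_candidates = hmm_candidates(shuffled_train, hmm, config.scoring)

    truth_merged = merge_intervals(train_truth_local)
    starts = [iv.start for iv in truth_merged]
    ends = [iv.end for iv in truth_merged]

    def overlaps_truth(iv: Interval) -> bool:
        import bisect

        k = bisect.bisect_right(starts, iv.end - 1) - 1
        return k >= 0 and ends[k] > iv.start

    labeled = [
        LabeledDetection(length, avg, 1)
        for iv, length, avg in real_candidates
        if overlaps_truth(iv)
    ]
    n_pos = len(labeled)
    if n_pos == 0:
        raise ValueError(
            "too few positives: no HMM detection overlaps the annotation on the "
            "training third"
        )
    labeled += [LabeledDetection(length, avg, -1) for _, length, avg in shuf_candidates]
    n_neg = len(labeled) - n_pos
    if n_neg == 0:
        raise ValueError(
            "no negatives: the HMM produced no detections on the shuffled "
            "training third, so the filter cannot be trained"
        )
    glm = train_glm(labeled, threshold=config.threshold)
    model = ModelFile(
        hmm=hmm,
        glm=glm,
        word_length=config.scoring.word_length,
        half_window=config.scoring.half_window,
    )
    model.validate()

    evaluations: list[SpanEvaluation] = []
    for k, name in enumerate(TrainingSplit.names):
        span = split.spans[k]
        span_seq = SequenceRecord(record.id, record.seq[span.start : span.end])
        truth = [
            replace(iv, start=iv.start - span.start, end=iv.end - span.start)
            for iv in split.annotations[k]
        ]
        dets = detect_record(span_seq, model)
        shuf = shuffle_sequence(span_seq, int(shuffle_seeds[k]))
        shuf_dets = detect_record(shuf, model)
        result = evaluate(dets, truth, shuf_dets, len(span_seq))
        evaluations.append(SpanEvaluation(name, result, len(dets)))
        logger.info(
            "%s third: sensitivity %.1f%%, FPR %.0f bp/Mbp, precision %.1f%%",
            name, result.sensitivity, result.fpr, result.precision,
        )

    report = TrainingReport(evaluations, n_glm_positives=n_pos, n_glm_negatives=n_neg)
    return model, report
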