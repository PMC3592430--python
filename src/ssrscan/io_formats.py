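"""File formats: FASTA in/out, masked FASTA, interval reports, model files.

Conventions
-----------
* In-memory coordinates are 0-based half-open.
* The tab-separated detection report stores 1-based inclusive coordinates,
  the common convention of genomic location tables; BED files (used for
  truth annotations) stay 0-based half-open as usual.
* Masked FASTA lower-cases the bases inside detections and upper-cases the
  rest, at 60 columns.
* Model files are plain, diffable text with named sections, and round-trip
  every parameter exactly (floats are written in shortest-repr form).
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
from Bio import SeqIO

from .core import DNA_ALPHABET, Interval, SequenceRecord
from .glm_filter import GlmFilter
from .hmm import TwoStateHMM

# IUPAC ambiguity codes (and U) degrade to N so real assemblies pass through.
_DEGRADE = set("RYSWKMBDHVU")


class ModelValidationError(ValueError):
    """A model file is missing a section or violates a probability invariant."""


def _normalize_seq(raw: str, rec_id: str) -> str:
    seq = raw.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        unknown = bad - _DEGRADE
        if unknown:
            raise ValueError(
                f"record {rec_id!r} contains non-nucleotide characters: {sorted(unknown)}"
            )
        warnings.warn(
            f"record {rec_id!r}: IUPAC codes {sorted(bad)} mapped to N",
            stacklevel=3,
        )
        seq = seq.translate(str.maketrans({c: "N" for c in bad}))
    return seq


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA file, normalized to upper-case ACGTN.

    Memory use is proportional to a single record.  Raises on empty
    sequences and duplicate identifiers.
    """
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: record with empty identifier")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        yield SequenceRecord(rec.id, _normalize_seq(seq, rec.id))
    if not seen:
        raise ValueError(f"{path}: no FASTA records found")


def _write_wrapped(handle: TextIO, seq: str, width: int = 60) -> None:
    for i in range(0, len(seq), width):
        handle.write(seq[i : i + width])
        handle.write("\n")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            _write_wrapped(fh, rec.seq)


def write_masked_fasta(
    records: Iterable[SequenceRecord],
    detections: Sequence[Interval],
    path: str | Path,
) -> None:
    """Write FASTA with detected microsatellites in lower case.

    Every base inside a detection is lower-cased; everything else is upper
    case.  A detection naming an unknown sequence id is an error.
    """
    by_seq: dict[str, list[Interval]] = {}
    for iv in detections:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    written: set[str] = set()
    with open(path, "w") as fh:
        for rec in records:
            written.add(rec.id)
            chars = np.frombuffer(rec.seq.upper().encode("ascii"), dtype=np.uint8).copy()
            for iv in by_seq.get(rec.id, ()):
                if iv.end > len(chars):
                    raise ValueError(
                        f"detection [{iv.start}, {iv.end}) exceeds record {rec.id!r} "
                        f"of length {len(chars)}"
                    )
                chars[iv.start : iv.end] |= 0x20  # ASCII lower-case
            fh.write(f">{rec.id}\n")
            _write_wrapped(fh, chars.tobytes().decode("ascii"))
    unknown = set(by_seq) - written
    if unknown:
        raise ValueError(f"detections reference unknown sequence ids: {sorted(unknown)}")


_REPORT_HEADER = "#seq_id\tstart\tend\tlogistic_value"


def write_intervals(detections: Sequence[Interval], path: str | Path) -> None:
    """Write the detection report: 1-based inclusive start/end plus logistic value.

    Requires the detections to be sorted by (seq_id, start) and
    non-overlapping within each sequence.
    """
    for prev, cur in zip(detections, detections[1:]):
        if (cur.seq_id, cur.start) < (prev.seq_id, prev.start):
            raise ValueError("detections must be sorted by (seq_id, start)")
        if cur.seq_id == prev.seq_id and cur.start < prev.end:
            raise ValueError(
                f"overlapping detections on {cur.seq_id!r}: "
                f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
            )
    with open(path, "w") as fh:
        fh.write(_REPORT_HEADER + "\n")
        for iv in detections:
            score = "." if iv.score is None else repr(float(iv.score))
            fh.write(f"{iv.seq_id}\t{iv.start + 1}\t{iv.end}\t{score}\n")


def read_intervals(path: str | Path) -> list[Interval]:
    """Read a detection report back into 0-based half-open intervals."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            seq_id, start, end, score = fields
            out.append(
                Interval(
                    seq_id,
                    int(start) - 1,
                    int(end),
                    None if score == "." else float(score),
                )
            )
    return out


def read_intervals_auto(path: str | Path) -> list[Interval]:
    """Read either a detection report (sniffed by its header line) or a BED."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(_REPORT_HEADER.split("\t", 1)[0]):
        return read_intervals(path)
    return read_bed(path)


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    """Write 0-based half-open BED (chrom, start, end[, score])."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.score is None:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.score!r}\n")


def read_bed(path: str | Path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED fields")
            score = None
            if len(fields) >= 4:
                try:
                    score = float(fields[3])
                except ValueError:
                    score = None
            out.append(Interval(fields[0], int(fields[1]), int(fields[2]), score))
    return out


@dataclass
class ModelFile:
    """Everything needed to run detection: scoring params, HMM and filter."""

    hmm: TwoStateHMM
    glm: GlmFilter
    word_length: int = 6
    half_window: int = 24

    @property
    def threshold(self) -> float:
        return self.glm.threshold

    def validate(self) -> None:
        try:
            self.hmm.validate()
        except ValueError as exc:
            raise ModelValidationError(f"hmm: {exc}") from exc
        if self.hmm.n != self.word_length:
            raise ModelValidationError(
                f"emission support 0..{self.hmm.n} does not match word_length "
                f"{self.word_length}"
            )
        if self.half_window < self.word_length:
            raise ModelValidationError("half_window must be >= word_length")


def _floats(values: Iterable[float]) -> str:
    return " ".join(repr(float(v)) for v in values)


def write_model(model: ModelFile, path: str | Path) -> None:
    model.validate()
    h, g = model.hmm, model.glm
    lines = [
        "# ssrscan model file, version 1",
        "[scoring]",
        f"word_length = {model.word_length}",
        f"half_window = {model.half_window}",
        "",
        "[hmm]",
        f"priors = {_floats(h.priors)}",
        f"transitions_from_nonms = {_floats(h.transitions[0])}",
        f"transitions_from_ms = {_floats(h.transitions[1])}",
        f"emissions_nonms = {_floats(h.emissions[0])}",
        f"emissions_ms = {_floats(h.emissions[1])}",
        "",
        "[glm]",
        f"length_mean = {g.mu[0]!r}",
        f"length_sd = {g.sigma[0]!r}",
        f"average_score_mean = {g.mu[1]!r}",
        f"average_score_sd = {g.sigma[1]!r}",
        f"weight_length = {g.weights[0]!r}",
        f"weight_average_score = {g.weights[1]!r}",
        f"bias = {g.bias!r}",
        f"threshold = {g.threshold!r}",
        "",
    ]
    Path(path).write_text("\n".join(lines))


def read_model(path: str | Path) -> ModelFile:
    parser = configparser.ConfigParser(inline_comment_prefixes=("#",))
    read = parser.read(str(path))
    if not read:
        raise ModelValidationError(f"cannot read model file {path}")

    def section(name: str) -> configparser.SectionProxy:
        if not parser.has_section(name):
            raise ModelValidationError(f"{path}: missing [{name}] section")
        return parser[name]

    def get(sec: configparser.SectionProxy, key: str) -> str:
        if key not in sec:
            raise ModelValidationError(f"{path}: missing field {key!r} in [{sec.name}]")
        return sec[key]

    sc = section("scoring")
    word_length = int(get(sc, "word_length"))
    half_window = int(get(sc, "half_window"))

    hm = section("hmm")
    try:
        hmm = TwoStateHMM(
            priors=[float(v) for v in get(hm, "priors").split()],
            transitions=[
                [float(v) for v in get(hm, "transitions_from_nonms").split()],
                [float(v) for v in get(hm, "transitions_from_ms").split()],
            ],
            emissions=[
                [float(v) for v in get(hm, "emissions_nonms").split()],
                [float(v) for v in get(hm, "emissions_ms").split()],
            ],
        )
    except ValueError as exc:
        raise ModelValidationError(f"{path}: [hmm]: {exc}") from exc

    gl = section("glm")
    try:
        glm = GlmFilter(
            mu=(float(get(gl, "length_mean")), float(get(gl, "average_score_mean"))),
            sigma=(float(get(gl, "length_sd")), float(get(gl, "average_score_sd"))),
            weights=(
                float(get(gl, "weight_length")),
                float(get(gl, "weight_average_score")),
            ),
            bias=float(get(gl, "bias")),
            threshold=float(get(gl, "threshold")),
        )
    except ValueError as exc:
        raise ModelValidationError(f"{path}: [glm]: {exc}") from exc

    model = ModelFile(hmm=hmm, glm=glm, word_length=word_length, half_window=half_window)
    model.validate()
    return model
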