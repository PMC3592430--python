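"""Synthetic chromosomes with planted microsatellites and exact truth labels.

The generator emulates the kind of annotated corpus the detector is trained
on: i.i.d. background sequence of configurable mono-nucleotide composition,
planted tandem repeats of 1-6 bp motifs with configurable copy numbers and
per-base substitution rates (substitution-only degradation, since the
scoring transform is gapless), optional N runs between loci, and an exact
annotation of every planted span.  Planted loci are kept at least
``min_gap`` bp apart (default twice the scoring half window) so flanking
windows of distinct loci do not interact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from bisect import bisect_left, insort

import numpy as np

from .core import Interval, SequenceRecord

UNIFORM = (0.25, 0.25, 0.25, 0.25)
# Emulates a strongly AT-biased genome (~80% A+T), the hardest shuffle-null case.
AT_RICH = (0.40, 0.10, 0.10, 0.40)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MsLocus:
    """One planted microsatellite: where it is and how it was built."""

    start: int
    end: int
    motif: str
    copies: int
    mutation_rate: float


@dataclass
class GenomeAnnotation:
    """Ground-truth annotation of the planted microsatellites."""

    seq_id: str
    loci: list[MsLocus] = field(default_factory=list)

    @property
    def intervals(self) -> list[Interval]:
        return [Interval(self.seq_id, l.start, l.end) for l in self.loci]


@dataclass
class SimConfig:
    """Conditions of the simulated chromosome.

    ms_density
        Expected fraction of the sequence inside planted loci (default
        0.011, matching the genome-scale rarity of microsatellites that
        the HMM's MS-state prior reflects).
    mutation_rate
        Either a fixed per-base substitution rate for every locus, or a
        (low, high) range from which each locus draws its own rate.  The
        default (0.0, 0.2) mixes perfect repeats with degenerate ones up
        to 20% diverged, the usual annotation cut-off for microsatellites.
    n_run_rate
        Expected number of N runs per bp (default 0: a gapless contig);
        run lengths are geometric with mean ``n_run_length``.
    """

    length: int = 1_000_000
    composition: tuple[float, float, float, float] = UNIFORM
    ms_density: float = 0.011
    motif_length_range: tuple[int, int] = (1, 6)
    copies_range: tuple[int, int] = (5, 50)
    mutation_rate: float | tuple[float, float] = (0.0, 0.2)
    n_run_rate: float = 0.0
    n_run_length: int = 50
    min_gap: int = 48
    seed: int = 0
    seq_id: str = "synthetic"

    def __post_init__(self) -> None:
        if abs(sum(self.composition) - 1.0) > 1e-9 or min(self.composition) < 0:
            raise ValueError("composition must be a probability vector over ACGT")
        lo, hi = self.motif_length_range
        if not (1 <= lo <= hi <= 6):
            raise ValueError("motif lengths must lie in [1, 6]")
        if not (0.0 <= self.ms_density < 1.0):
            raise ValueError("ms_density must lie in [0, 1)")
        rates = (
            (self.mutation_rate, self.mutation_rate)
            if np.isscalar(self.mutation_rate)
            else tuple(self.mutation_rate)
        )
        if not (0.0 <= rates[0] <= rates[1] <= 1.0):
            raise ValueError("mutation rates must lie in [0, 1]")


def degrade_locus(
    motif: str, copies: int, rate: float, rng: np.random.Generator | int
) -> str:
    """Tandem-repeat a motif and substitute each base independently at ``rate``.

    A substituted base is drawn uniformly from the three other bases, so
    rate 1 changes every position.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    arr = np.frombuffer((motif * copies).encode("ascii"), dtype=np.uint8).copy()
    if rate > 0:
        hit = np.flatnonzero(rng.random(arr.size) < rate)
        for i in hit:
            others = _BASES[_BASES != arr[i]]
            arr[i] = others[rng.integers(3)]
    return arr.tobytes().decode("ascii")


def _place(rng: np.random.Generator, length: int, size: int, gap: int,
           occupied: list[tuple[int, int]], attempts: int = 200) -> int | None:
    """Uniform non-overlapping placement with a minimum gap; None if crowded."""
    for _ in range(attempts):
        start = int(rng.integers(0, length - size + 1))
        lo, hi = start - gap, start + size + gap
        idx = bisect_left(occupied, (lo,))
        clash = False
        for s, e in occupied[max(0, idx - 1) :]:
            if s >= hi:
                break
            if e > lo:
                clash = True
                break
        if not clash:
            return start
    return None


def simulate_chromosome(config: SimConfig) -> tuple[SequenceRecord, GenomeAnnotation]:
    """Draw background sequence, plant loci to the target density, add N runs."""
    rng = np.random.default_rng(config.seed)
    seq = rng.choice(_BASES, size=config.length, p=np.asarray(config.composition))
    annotation = GenomeAnnotation(config.seq_id)
    occupied: list[tuple[int, int]] = []

    target_bp = config.ms_density * config.length
    planted_bp = 0
    scalar_rate = np.isscalar(config.mutation_rate)
    failures = 0
    while planted_bp < target_bp:
        motif_len = int(rng.integers(config.motif_length_range[0],
                                     config.motif_length_range[1] + 1))
        motif = rng.choice(_BASES, size=motif_len).tobytes().decode("ascii")
        copies = int(rng.integers(config.copies_range[0], config.copies_range[1] + 1))
        rate = (
            float(config.mutation_rate)
            if scalar_rate
            else float(rng.uniform(*config.mutation_rate))
        )
        locus = degrade_locus(motif, copies, rate, rng)
        if len(locus) > config.length:
            continue
        start = _place(rng, config.length, len(locus), config.min_gap, occupied)
        if start is None:
            failures += 1
            if failures > 50:
                raise ValueError(
                    f"cannot reach ms_density {config.ms_density} in {config.length} bp "
                    f"with min_gap {config.min_gap}"
                )
            continue
        failures = 0
        seq[start : start + len(locus)] = np.frombuffer(
            locus.encode("ascii"), dtype=np.uint8
        )
        insort(occupied, (start, start + len(locus)))
        annotation.loci.append(MsLocus(start, start + len(locus), motif, copies, rate))
        planted_bp += len(locus)

    if config.n_run_rate > 0:
        n_runs = rng.poisson(config.n_run_rate * config.length)
        for _ in range(n_runs):
            run = 1 + int(rng.geometric(1.0 / max(1, config.n_run_length)))
            run = min(run, config.length)
            start = _place(rng, config.length, run, config.min_gap, occupied)
            if start is None:
                continue
            seq[start : start + run] = ord("N")
            insort(occupied, (start, start + run))

    annotation.loci.sort(key=lambda l: l.start)
    record = SequenceRecord(config.seq_id, seq.tobytes().decode("ascii"))
    return record, annotation
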