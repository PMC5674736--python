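"""Perfect and imperfect microsatellite detection.

The detector finds tandem repeats of 1–6 bp primitive motifs whose total
tract length is at least 15 bp.  Perfect tracts are maximal runs in which
every base equals the base one period earlier.  Imperfect tracts are found by
seed-and-extend: a perfect seed (at least ``seed_min_copies`` copies and
``seed_min_length`` bp) is extended in both directions against the periodic
expectation anchored at the seed, scoring +1 per match and
−``mismatch_penalty`` per mismatch, stopping once the running score falls
``max_score_drop`` below its maximum; the reported tract is trimmed back to
the maximal-score extent.

Ambiguous bases (N) act as hard boundaries: no tract spans an N, and all
coordinates stay in the original sequence frame (0-based half-open
internally; 1-based inclusive in written tables).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .motifs import canonicalize, is_primitive

__all__ = [
    "GenomeRecord",
    "SsrLocus",
    "DetectionParams",
    "split_on_ambiguity",
    "find_perfect_ssrs",
    "find_imperfect_ssrs",
    "find_all_ssrs",
    "resolve_overlaps",
]

_VALID = set("ACGTN")


@dataclass
class GenomeRecord:
    """One sequence (chromosome/scaffold/genome) plus identity metadata."""

    seq_id: str
    sequence: str
    species: str | None = None
    genus: str | None = None
    family: str | None = None
    order: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        """GC fraction over unambiguous bases only."""
        s = self.sequence
        gc = s.count("G") + s.count("C")
        at = s.count("A") + s.count("T")
        if gc + at == 0:
            return float("nan")
        return gc / (gc + at)


@dataclass(frozen=True)
class SsrLocus:
    """One detected (or planted) microsatellite locus.

    Coordinates are 0-based half-open on the forward strand.  ``motif`` is the
    periodic pattern phased to the tract start; ``canonical_class`` is its
    rotation/reverse-complement class name.  ``score`` is
    matches − mismatch_penalty × mismatches over the tract.
    """

    seq_id: str
    start: int
    end: int
    motif: str
    canonical_class: str
    motif_len: int
    tract_length: int
    n_mismatches: int
    perfect: bool
    score: int

    @classmethod
    def make(
        cls,
        seq_id: str,
        start: int,
        end: int,
        motif: str,
        n_mismatches: int,
        mismatch_penalty: int = 5,
    ) -> "SsrLocus":
        length = end - start
        matches = length - n_mismatches
        return cls(
            seq_id=seq_id,
            start=start,
            end=end,
            motif=motif,
            canonical_class=canonicalize(motif),
            motif_len=len(motif),
            tract_length=length,
            n_mismatches=n_mismatches,
            perfect=n_mismatches == 0,
            score=matches - mismatch_penalty * n_mismatches,
        )

    def overlaps(self, other: "SsrLocus") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class DetectionParams:
    """Tunable detector parameters.

    The 15-bp minimum tract and the 1–6 bp motif range are the defining
    constraints of the analysis; the seed and scoring defaults govern only the
    imperfect search and are configurable.
    """

    min_tract_length: int = 15
    seed_min_copies: int = 3
    seed_min_length: int = 8
    mismatch_penalty: int = 5
    max_score_drop: int = 5
    motif_lengths: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

    def __post_init__(self) -> None:
        for name in ("min_tract_length", "seed_min_copies", "seed_min_length",
                     "mismatch_penalty", "max_score_drop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_tract_length < self.seed_min_length:
            raise ValueError("min_tract_length must be >= seed_min_length")
        ks = tuple(sorted(set(self.motif_lengths)))
        if not ks or any(k < 1 or k > 6 for k in ks):
            raise ValueError("motif_lengths must be a non-empty subset of 1..6")
        object.__setattr__(self, "motif_lengths", ks)

    def seed_bp(self, k: int) -> int:
        return max(self.seed_min_length, self.seed_min_copies * k)


def split_on_ambiguity(sequence: str) -> list[tuple[int, str]]:
    """Split a sequence on runs of N into (offset, substring) segments.

    Offsets index into the original sequence, so downstream coordinates stay
    in the original frame.  A sequence of only Ns yields an empty list.
    """
    return [(m.start(), m.group(0)) for m in re.finditer(r"[^N]+", sequence.upper())]


def _validate_sequence(record: GenomeRecord) -> None:
    bad = set(record.sequence) - _VALID
    if bad:
        raise ValueError(
            f"sequence {record.seq_id!r} contains invalid symbol(s): {sorted(bad)!r}"
        )


def _encode(segment: str) -> np.ndarray:
    return np.frombuffer(segment.encode("ascii"), dtype=np.uint8)


def _perfect_runs(codes: np.ndarray, k: int) -> Iterator[tuple[int, int]]:
    """Maximal period-k runs as (start, end) tract coordinates, end-start > k."""
    n = codes.size
    if n <= k:
        return
    m = codes[k:] == codes[:-k]
    if not m.any():
        return
    mi = m.astype(np.int8)
    d = np.diff(mi)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        ends = np.concatenate((ends, [m.size]))
    for s, e in zip(starts, ends):
        yield int(s), int(e) + k  # tract spans [s, e+k)


def find_perfect_ssrs(record: GenomeRecord, params: DetectionParams | None = None) -> list[SsrLocus]:
    """All maximal perfect tracts of primitive 1–6 bp motifs, >= 15 bp.

    A maximal period-k run whose leading k-mer is non-primitive (e.g. "AA")
    is covered at the smaller period and not reported at k.
    """
    params = params or DetectionParams()
    _validate_sequence(record)
    loci: list[SsrLocus] = []
    for offset, segment in split_on_ambiguity(record.sequence):
        codes = _encode(segment)
        for k in params.motif_lengths:
            for s, e in _perfect_runs(codes, k):
                if e - s < params.min_tract_length:
                    continue
                motif = segment[s : s + k]
                if not is_primitive(motif):
                    continue
                loci.append(
                    SsrLocus.make(
                        record.seq_id, offset + s, offset + e, motif,
                        n_mismatches=0, mismatch_penalty=params.mismatch_penalty,
                    )
                )
    loci.sort(key=lambda l: (l.start, l.motif_len))
    return loci


def _extend_seed(
    codes: np.ndarray,
    motif_codes: np.ndarray,
    seed_start: int,
    seed_end: int,
    params: DetectionParams,
) -> tuple[int, int]:
    """Extend a perfect seed both ways; return trimmed (start, end)."""
    k = motif_codes.size
    n = codes.size
    penalty = params.mismatch_penalty
    drop = params.max_score_drop
    anchor = seed_start

    # rightward
    score = best = seed_end - seed_start
    best_end = seed_end
    pos = seed_end
    while pos < n:
        if codes[pos] == motif_codes[(pos - anchor) % k]:
            score += 1
        else:
            score -= penalty
        pos += 1
        if score > best:
            best = score
            best_end = pos
        elif best - score > drop:
            break

    # leftward
    score = best = seed_end - seed_start
    best_start = seed_start
    pos = seed_start - 1
    while pos >= 0:
        if codes[pos] == motif_codes[(pos - anchor) % k]:
            score += 1
        else:
            score -= penalty
        if score > best:
            best = score
            best_start = pos
        elif best - score > drop:
            break
        pos -= 1

    return best_start, best_end


def find_imperfect_ssrs(record: GenomeRecord, params: DetectionParams | None = None) -> list[SsrLocus]:
    """Seed-and-extend search for tracts allowing mismatches.

    The returned call set is unified: tracts whose extension accumulates zero
    mismatches coincide with perfect tracts at the same locus.  Perfect tracts
    too short to seed (below ``seed_min_copies`` copies) are not returned here;
    use :func:`find_all_ssrs` for the union.
    """
    params = params or DetectionParams()
    _validate_sequence(record)
    loci: list[SsrLocus] = []
    for offset, segment in split_on_ambiguity(record.sequence):
        codes = _encode(segment)
        seen: set[tuple[int, int, int]] = set()
        for k in params.motif_lengths:
            seed_bp = params.seed_bp(k)
            for s, e in _perfect_runs(codes, k):
                if e - s < seed_bp:
                    continue
                motif = segment[s : s + k]
                if not is_primitive(motif):
                    continue
                motif_codes = _encode(motif)
                start, end = _extend_seed(codes, motif_codes, s, e, params)
                if end - start < params.min_tract_length:
                    continue
                key = (k, start, end)
                if key in seen:
                    continue
                seen.add(key)
                # periodic expectation anchored at the seed, phased to start
                phase = (start - s) % k
                phased = motif[phase:] + motif[:phase]
                expected = np.resize(_encode(phased), end - start)
                nm = int(np.count_nonzero(codes[start:end] != expected))
                loci.append(
                    SsrLocus.make(
                        record.seq_id, offset + start, offset + end, phased,
                        n_mismatches=nm, mismatch_penalty=params.mismatch_penalty,
                    )
                )
    loci.sort(key=lambda l: (l.start, l.motif_len))
    return loci


def find_all_ssrs(record: GenomeRecord, params: DetectionParams | None = None) -> list[SsrLocus]:
    """Unified non-redundant call set: perfect ∪ imperfect, overlap-resolved."""
    params = params or DetectionParams()
    candidates = find_imperfect_ssrs(record, params)
    seen = {(l.motif_len, l.start, l.end) for l in candidates}
    for l in find_perfect_ssrs(record, params):
        if (l.motif_len, l.start, l.end) not in seen:
            candidates.append(l)
    return resolve_overlaps(candidates)


def resolve_overlaps(loci: Sequence[SsrLocus]) -> list[SsrLocus]:
    """Greedy non-redundant subset: higher score wins; ties prefer the
    smaller motif length, then the smaller start.  Output sorted by start."""
    chosen: list[SsrLocus] = []
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for loc in sorted(loci, key=lambda l: (-l.score, l.motif_len, l.start, l.end)):
        intervals = by_seq.setdefault(loc.seq_id, [])
        if any(loc.start < e and s < loc.end for s, e in intervals):
            continue
        intervals.append((loc.start, loc.end))
        chosen.append(loc)
    chosen.sort(key=lambda l: (l.seq_id, l.start))
    return chosen
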