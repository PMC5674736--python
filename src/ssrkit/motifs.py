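"""Canonical motif classes for microsatellites.

A microsatellite motif is read off the genome in an arbitrary phase and on an
arbitrary strand, so the natural unit of comparison is the equivalence class
of a motif under cyclic rotation and reverse complement.  Each class is named
by its lexicographically smallest member (A < C < G < T), which reproduces the
representatives conventionally printed in comparative SSR surveys (e.g. the
dinucleotide groups AG = {AG, GA, CT, TC} and AC = {AC, CA, GT, TG}, or the
trinucleotide group AAT = {AAT, ATA, TAA, ATT, TAT, TTA}).

Only *primitive* motifs (not a repetition of a shorter motif) form classes:
an (ATAT)n tract is a dinucleotide repeat, never a tetranucleotide one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Iterable

__all__ = [
    "MotifClass",
    "reverse_complement",
    "primitive_motif",
    "is_primitive",
    "canonicalize",
    "enumerate_classes",
    "classify_perfection",
    "PERFECTION_SCHEMES",
]

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_motif(motif: str) -> None:
    if not motif:
        raise ValueError("motif must be a non-empty DNA string")
    bad = set(motif) - set(_ALPHABET)
    if bad:
        raise ValueError(f"motif {motif!r} contains non-ACGT symbol(s): {sorted(bad)}")


def primitive_motif(motif: str) -> str:
    """Shortest string whose repetition generates ``motif``.

    ``primitive_motif("ATAT") == "AT"``; a motif that is already primitive is
    returned unchanged.
    """
    _validate_motif(motif)
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif[:p] * (n // p) == motif:
            return motif[:p]
    return motif


def is_primitive(motif: str) -> bool:
    return primitive_motif(motif) == motif


def _rotations(motif: str) -> Iterable[str]:
    return (motif[i:] + motif[:i] for i in range(len(motif)))


def canonicalize(motif: str) -> str:
    """Name of the rotation/reverse-complement class containing ``motif``.

    The name is the lexicographically smallest string among all rotations of
    the motif and all rotations of its reverse complement.  Raises
    ``ValueError`` for non-primitive input: reduce with
    :func:`primitive_motif` first.
    """
    _validate_motif(motif)
    if not is_primitive(motif):
        raise ValueError(
            f"motif {motif!r} is not primitive; reduce with primitive_motif() first"
        )
    rc = reverse_complement(motif)
    return min(min(_rotations(motif)), min(_rotations(rc)))


@dataclass(frozen=True)
class MotifClass:
    """A rotation + reverse-complement equivalence class of primitive motifs."""

    canonical: str
    members: frozenset[str]
    k: int

    def __post_init__(self) -> None:
        if self.canonical not in self.members:
            raise ValueError("canonical representative must be a member")

    def __contains__(self, motif: str) -> bool:
        return motif in self.members


@lru_cache(maxsize=None)
def enumerate_classes(k: int) -> tuple[MotifClass, ...]:
    """Partition of all primitive ``k``-mers into canonical classes.

    Classes are returned sorted by canonical representative.  Cached per k.
    """
    if not 1 <= k <= 6:
        raise ValueError(f"motif length must be in 1..6, got {k}")
    groups: dict[str, set[str]] = {}
    for tup in product(_ALPHABET, repeat=k):
        motif = "".join(tup)
        if not is_primitive(motif):
            continue
        groups.setdefault(canonicalize(motif), set()).add(motif)
    return tuple(
        MotifClass(canonical=c, members=frozenset(members), k=k)
        for c, members in sorted(groups.items())
    )


@lru_cache(maxsize=None)
def _class_lookup(k: int) -> dict[str, str]:
    table: dict[str, str] = {}
    for cls in enumerate_classes(k):
        for m in cls.members:
            table[m] = cls.canonical
    return table


def class_of(motif: str) -> str:
    """Canonical class name for any observed motif (reduced if non-primitive)."""
    motif = primitive_motif(motif.upper())
    return _class_lookup(len(motif))[motif]


PERFECTION_SCHEMES = ("any_mismatch", "length_stratified")


def classify_perfection(locus, scheme: str = "any_mismatch") -> str:
    """Label a locus "perfect" or "imperfect".

    Two schemes are supported.  ``any_mismatch`` (default): a tract is
    imperfect iff it contains at least one mismatch against the periodic
    pattern.  ``length_stratified``: a tract is imperfect iff it is >= 30 bp
    with 1-3 mismatches, or <= 30 bp with >= 3 mismatches; tracts matching
    neither stratum fall back to the any-mismatch rule.  The stratified rule
    is kept for sensitivity analysis only — under it a short tract with a
    single mismatch would otherwise be neither perfect nor imperfect.
    """
    if scheme not in PERFECTION_SCHEMES:
        raise ValueError(f"unknown perfection scheme {scheme!r}; choose from {PERFECTION_SCHEMES}")
    nm = locus.n_mismatches
    if nm == 0:
        return "perfect"
    if scheme == "any_mismatch":
        return "imperfect"
    length = locus.tract_length
    if length >= 30 and 1 <= nm <= 3:
        return "imperfect"
    if length <= 30 and nm >= 3:
        return "imperfect"
    return "imperfect"  # fallback: any mismatch
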