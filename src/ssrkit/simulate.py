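"""Synthetic genomes with planted microsatellites and gene models.

Every downstream stage is verified against genomes where the truth is known
by construction.  The generator plants perfect and imperfect repeat tracts
into an i.i.d. background at a target GC, then scrubs the background so that
no incidental perfect repeat >= 15 bp survives outside the planted tracts,
and forces the two bases flanking each tract to break the periodic pattern.
Together with the mismatch-placement rules below this makes the planted truth
unambiguous: the maximal repeat tract around each plant is exactly the
planted interval, with exactly the planted mismatch count.

Mismatch placement inside imperfect tracts: substitutions only, kept at
least max(k, 6) bp from either tract end, pairwise separated by at least
max(3k, 8) + 1 bp, and leaving at least one clean run of max(3k, 8) bp
(one seedable stretch).  Real imperfect microsatellites carry sparse
mismatches (on the order of 1–3% of tract bases), so isolated substitutions
are the realistic regime as well as the unambiguous one.

Cohorts: families of genomes share a mean composition over motif classes;
per-genome compositions are Dirichlet draws around the family mean, so that
family structure is recoverable by composition-divergence clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detect import GenomeRecord, SsrLocus
from .motifs import is_primitive
from .regions import GeneModel

__all__ = [
    "PlantedRepeat",
    "SyntheticGenomeSpec",
    "CohortSpec",
    "SimulatedGenome",
    "generate_genome",
    "generate_cohort",
    "random_planted_repeats",
    "random_gene_models",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MIN_PLANT_SEPARATION = 20


@dataclass(frozen=True)
class PlantedRepeat:
    """Ground truth for one planted tract.

    ``mismatch_positions`` are offsets within the tract at which the planted
    base is substituted by a different base.  ``truth_length`` is
    copies × motif length.
    """

    motif: str
    copies: int
    insert_pos: int
    mismatch_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= len(self.motif) <= 6:
            raise ValueError(f"motif length must be 1..6, got {self.motif!r}")
        if not is_primitive(self.motif):
            raise ValueError(f"planted motif {self.motif!r} is not primitive")
        if self.copies < 1:
            raise ValueError("copies must be positive")
        k = len(self.motif)
        pos = tuple(sorted(set(self.mismatch_positions)))
        object.__setattr__(self, "mismatch_positions", pos)
        for p in pos:
            if not k <= p < self.truth_length - k:
                raise ValueError(
                    f"mismatch offset {p} in the boundary copies of a "
                    f"{self.truth_length}-bp tract (must lie in [{k}, {self.truth_length - k}))"
                )

    @property
    def truth_length(self) -> int:
        return self.copies * len(self.motif)

    @property
    def end(self) -> int:
        return self.insert_pos + self.truth_length


@dataclass
class SyntheticGenomeSpec:
    genome_length: int
    gc_fraction: float = 0.35
    planted: list[PlantedRepeat] = field(default_factory=list)
    gene_models: list[GeneModel] = field(default_factory=list)
    rng_seed: int = 0
    seq_id: str = "synth1"

    def validate(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        planted = sorted(self.planted, key=lambda p: p.insert_pos)
        prev_end = -_MIN_PLANT_SEPARATION
        for pr in planted:
            if pr.insert_pos < 0 or pr.end > self.genome_length:
                raise ValueError(
                    f"planted repeat {pr.motif}×{pr.copies} at {pr.insert_pos} "
                    f"does not fit in a {self.genome_length}-bp genome"
                )
            if pr.insert_pos - prev_end < _MIN_PLANT_SEPARATION:
                raise ValueError(
                    f"planted repeats overlap or sit closer than "
                    f"{_MIN_PLANT_SEPARATION} bp near position {pr.insert_pos}"
                )
            prev_end = pr.end
        for gm in self.gene_models:
            if gm.end > self.genome_length:
                raise ValueError(f"gene {gm.gene_id} extends past the genome end")


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """i.i.d. bases as ASCII codes at the target GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _scan_runs_ge(codes: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """All maximal period-k (k=1..6) runs of tract length >= min_len."""
    runs: list[tuple[int, int]] = []
    n = codes.size
    for k in range(1, 7):
        if n <= k:
            continue
        m = codes[k:] == codes[:-k]
        if not m.any():
            continue
        d = np.diff(m.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if m[0]:
            starts = np.concatenate(([0], starts))
        if m[-1]:
            ends = np.concatenate((ends, [m.size]))
        for s, e in zip(starts, ends):
            if e + k - s >= min_len:
                runs.append((int(s), int(e) + k))
    return runs


def generate_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[str, list[SsrLocus], list[GeneModel]]:
    """Build the sequence, truth loci and gene models for one genome.

    Post-conditions: the sequence has the requested length; each planted
    tract appears at its coordinates with exactly its mismatch count; no
    perfect repeat >= 15 bp survives outside the planted intervals (enforced
    by scan-and-regenerate); tract flanks break the periodic continuation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.genome_length
    codes = _background(rng, n, spec.gc_fraction)

    planted = sorted(spec.planted, key=lambda p: p.insert_pos)
    protected = np.zeros(n, dtype=bool)
    flank_rules: list[tuple[int, int]] = []  # (position, forbidden base code)

    for pr in planted:
        k = len(pr.motif)
        tract = np.resize(
            np.frombuffer(pr.motif.encode("ascii"), dtype=np.uint8), pr.truth_length
        )
        for p in pr.mismatch_positions:
            alternatives = _BASES[_BASES != tract[p]]
            tract[p] = rng.choice(alternatives)
        codes[pr.insert_pos : pr.end] = tract
        protected[pr.insert_pos : pr.end] = True
        motif_codes = np.frombuffer(pr.motif.encode("ascii"), dtype=np.uint8)
        if pr.insert_pos > 0:
            flank_rules.append((pr.insert_pos - 1, int(motif_codes[(-1) % k])))
        if pr.end < n:
            flank_rules.append((pr.end, int(motif_codes[pr.truth_length % k])))

    def enforce_flanks() -> None:
        for pos, forbidden in flank_rules:
            if protected[pos]:
                continue  # adjacent plants; separation rule prevents this
            if codes[pos] == forbidden:
                codes[pos] = rng.choice(_BASES[_BASES != forbidden])

    enforce_flanks()
    for _ in range(300):
        offending: set[int] = set()
        for s, e in _scan_runs_ge(codes, 15):
            if protected[s:e].all():
                continue
            offending.update(
                int(i) for i in range(s, e) if not protected[i]
            )
        if not offending:
            break
        idx = np.fromiter(sorted(offending), dtype=np.int64)
        codes[idx] = _background(rng, idx.size, spec.gc_fraction)
        enforce_flanks()
    else:
        raise RuntimeError("background regeneration did not converge")

    sequence = bytes(codes).decode("ascii")

    truth = [
        SsrLocus.make(
            spec.seq_id,
            pr.insert_pos,
            pr.end,
            pr.motif,
            n_mismatches=len(pr.mismatch_positions),
        )
        for pr in planted
    ]
    return sequence, truth, list(spec.gene_models)


# ---------------------------------------------------------------------------
# random plant construction


def _random_primitive_motif(rng: np.random.Generator, k: int) -> str:
    while True:
        motif = "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))
        if is_primitive(motif):
            return motif


def _sample_mismatch_positions(
    rng: np.random.Generator, k: int, length: int, n_mismatches: int
) -> tuple[int, ...]:
    """Sample substitution offsets under the unambiguity rules.

    Falls back to fewer mismatches when the tract cannot host the requested
    number under the margin/separation constraints.
    """
    margin = max(k, 6)
    min_sep = max(3 * k, 8) + 1
    seed_run = max(3 * k, 8)
    lo, hi = margin, length - margin
    m = n_mismatches
    while m > 0:
        if hi - lo >= m:
            for _ in range(300):
                pos = np.sort(rng.choice(np.arange(lo, hi), size=m, replace=False))
                if m > 1 and np.diff(pos).min() < min_sep:
                    continue
                segments = [pos[0]] + list(np.diff(pos) - 1) + [length - 1 - pos[-1]]
                if max(segments) >= seed_run:
                    return tuple(int(p) for p in pos)
        m -= 1
    return ()


def _plants_for_ks(
    rng: np.random.Generator,
    k_list: Sequence[int],
    frac_imperfect: float,
    *,
    min_gap: int = 25,
    max_gap: int = 150,
    start_at: int = 30,
) -> tuple[list[PlantedRepeat], int]:
    """Lay plants of the given motif lengths left to right.

    Perfect tracts target 16–30 bp and imperfect tracts 28–72 bp with 1–3
    sparse mismatches, matching the length regimes typically reported for
    perfect vs imperfect microsatellites.  Returns (plants, genome length).
    """
    plants: list[PlantedRepeat] = []
    pos = start_at
    for k in k_list:
        k = int(k)
        motif = _random_primitive_motif(rng, k)
        if rng.random() < frac_imperfect:
            target = int(rng.integers(28, 73))
            copies = max(-(-target // k), 5)
            length = copies * k
            n_mm = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
            mm = _sample_mismatch_positions(rng, k, length, n_mm)
        else:
            target = int(rng.integers(16, 31))
            copies = max(-(-target // k), -(-16 // k))
            mm = ()
        plants.append(
            PlantedRepeat(motif=motif, copies=copies, insert_pos=pos, mismatch_positions=mm)
        )
        pos += plants[-1].truth_length + int(rng.integers(min_gap, max_gap))
    return plants, pos + 30


def random_planted_repeats(
    rng: np.random.Generator,
    n: int,
    *,
    frac_imperfect: float = 0.25,
    motif_lengths: Sequence[int] = (1, 2, 3, 4, 5, 6),
    min_gap: int = 25,
    max_gap: int = 150,
    start_at: int = 30,
) -> tuple[list[PlantedRepeat], int]:
    """Draw ``n`` plants with uniform motif lengths; return (plants, length)."""
    k_list = rng.choice(list(motif_lengths), size=n)
    return _plants_for_ks(
        rng, k_list, frac_imperfect, min_gap=min_gap, max_gap=max_gap, start_at=start_at
    )


def random_gene_models(
    rng: np.random.Generator,
    genome_length: int,
    n_genes: int,
    *,
    seq_id: str = "synth1",
    min_intron: int = 50,
) -> list[GeneModel]:
    """Non-overlapping single-transcript genes with 1–5 exons each."""
    models: list[GeneModel] = []
    pos = int(rng.integers(100, 400))
    for i in range(n_genes):
        n_exons = int(rng.integers(1, 6))
        exon_lens = rng.integers(60, 300, size=n_exons)
        intron_lens = rng.integers(min_intron, min_intron + 200, size=max(n_exons - 1, 0))
        start = pos
        exons = []
        cur = start
        for j, el in enumerate(exon_lens):
            exons.append((cur, cur + int(el)))
            cur += int(el)
            if j < n_exons - 1:
                cur += int(intron_lens[j])
        end = cur
        if end > genome_length - 100:
            break
        models.append(
            GeneModel(gene_id=f"gene{i + 1}", seq_id=seq_id, start=start, end=end, exons=exons)
        )
        pos = end + int(rng.integers(150, 500))
    return models


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Family-structured cohort of synthetic genomes.

    ``family_composition_means`` is an (n_families × n_features) matrix of
    per-family mean proportions over the feature space (by default the five
    motif-length classes 2..6, the feature space of the headline clustering).
    Per-genome proportions are Dirichlet(concentration × mean) draws;
    ``concentration = inf`` gives every genome exactly the family mean.
    """

    n_families: int
    genomes_per_family: int
    family_composition_means: np.ndarray
    concentration: float = 200.0
    ssrs_per_genome: int = 150
    rng_seed: int = 0
    feature_ks: tuple[int, ...] = (2, 3, 4, 5, 6)
    frac_imperfect: float = 0.25
    gc_fraction: float = 0.35
    n_genes: int = 0

    def validate(self) -> None:
        if self.n_families < 1 or self.genomes_per_family < 1:
            raise ValueError("cohort must contain at least one genome")
        means = np.asarray(self.family_composition_means, dtype=float)
        if means.shape != (self.n_families, len(self.feature_ks)):
            raise ValueError(
                f"family_composition_means must have shape "
                f"({self.n_families}, {len(self.feature_ks)}), got {means.shape}"
            )
        if (means < 0).any():
            raise ValueError("composition means must be non-negative")
        if not np.allclose(means.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each composition mean must sum to 1")
        if self.ssrs_per_genome < 1:
            raise ValueError("ssrs_per_genome must be positive")


@dataclass
class SimulatedGenome:
    record: GenomeRecord
    truth: list[SsrLocus]
    gene_models: list[GeneModel]
    family: str


def _draw_proportions(
    rng: np.random.Generator, mean: np.ndarray, concentration: float
) -> np.ndarray:
    if math.isinf(concentration):
        return mean.copy()
    props = np.zeros_like(mean)
    support = mean > 0
    props[support] = rng.dirichlet(concentration * mean[support])
    return props


def generate_cohort(cohort: CohortSpec) -> list[SimulatedGenome]:
    """Generate all genomes of a family-structured cohort.

    Each genome's planted motif-class counts are a multinomial draw around a
    Dirichlet perturbation of its family's mean composition.
    """
    cohort.validate()
    rng = np.random.default_rng(cohort.rng_seed)
    means = np.asarray(cohort.family_composition_means, dtype=float)
    ks = np.asarray(cohort.feature_ks)
    out: list[SimulatedGenome] = []
    for f in range(cohort.n_families):
        family = f"fam{f + 1}"
        for g in range(cohort.genomes_per_family):
            gid = f"{family}_g{g + 1}"
            props = _draw_proportions(rng, means[f], cohort.concentration)
            counts = rng.multinomial(cohort.ssrs_per_genome, props)
            k_list = np.repeat(ks, counts)
            rng.shuffle(k_list)
            plants, length = _plants_for_ks(rng, k_list, cohort.frac_imperfect)
            spec = SyntheticGenomeSpec(
                genome_length=length,
                gc_fraction=cohort.gc_fraction,
                planted=plants,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
                seq_id=gid,
            )
            if cohort.n_genes:
                spec.gene_models = random_gene_models(
                    rng, length, cohort.n_genes, seq_id=gid
                )
            sequence, truth, models = generate_genome(spec)
            record = GenomeRecord(seq_id=gid, sequence=sequence, family=family)
            out.append(SimulatedGenome(record=record, truth=truth,
                                       gene_models=models, family=family))
    return out
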