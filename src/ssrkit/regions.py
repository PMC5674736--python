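"""Assign microsatellite loci to genomic-region categories.

Five mutually exclusive, exhaustive categories are used: ``exon``,
``intron``, ``intergenic``, ``exon_intron_spanning`` (fully genic but
crossing an exon–intron boundary) and ``genic_intergenic_spanning``
(overlapping a gene span but extending outside all gene spans).  A base is
exonic if it is exonic in ANY gene (exons from multiple transcripts are
unioned; strand is ignored).  Overlap means >= 1 shared base; all interval
arithmetic is half-open.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = (
    "exon",
    "intron",
    "intergenic",
    "exon_intron_spanning",
    "genic_intergenic_spanning",
)

__all__ = [
    "CATEGORIES",
    "GeneModel",
    "build_gene_models",
    "classify_region",
    "classify_regions",
    "tabulate_regions",
    "region_table",
]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and non-overlapping."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GeneModel:
    """One gene: span plus the union of exon intervals over its transcripts.

    Coordinates are 0-based half-open.  Introns are the within-span gaps
    between exons.
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = merge_intervals(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id!r}: exon [{s}, {e}) outside gene span "
                    f"[{self.start}, {self.end})"
                )

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        prev = self.start
        for s, e in self.exons:
            if s > prev:
                out.append((prev, s))
            prev = e
        if prev < self.end:
            out.append((prev, self.end))
        return out


def build_gene_models(gff3: str, *, from_string: bool = False) -> list[GeneModel]:
    """Parse GFF3 (path, or literal text with ``from_string=True``) into gene models.

    Exons from all transcripts of a gene are unioned.  A gene with no exon
    features is treated as a single exon spanning its full span, with a
    warning.  GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open.
    """
    import gffutils

    db = gffutils.create_db(
        gff3,
        ":memory:",
        from_string=from_string,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="exon")
        ]
        if not exons:
            logger.warning(
                "gene %s has no exon features; treating as single-exon", gene.id
            )
            exons = [(gene.start - 1, gene.end)]
        models.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                exons=exons,
            )
        )
    return models


class _Union:
    """Merged half-open intervals with O(log n) coverage queries."""

    def __init__(self, intervals: Iterable[tuple[int, int]]):
        merged = merge_intervals(intervals)
        self.starts = [s for s, _ in merged]
        self.ends = [e for _, e in merged]

    def coverage(self, start: int, end: int) -> int:
        """Number of bases of [start, end) covered by the union."""
        total = 0
        i = bisect_right(self.ends, start)
        while i < len(self.starts) and self.starts[i] < end:
            total += min(end, self.ends[i]) - max(start, self.starts[i])
            i += 1
        return total


class RegionIndex:
    """Precomputed per-sequence gene-span and exon unions for classification."""

    def __init__(self, models: Sequence[GeneModel]):
        spans: dict[str, list[tuple[int, int]]] = {}
        exons: dict[str, list[tuple[int, int]]] = {}
        for m in models:
            spans.setdefault(m.seq_id, []).append((m.start, m.end))
            exons.setdefault(m.seq_id, []).extend(m.exons)
        self._genic = {sid: _Union(iv) for sid, iv in spans.items()}
        self._exonic = {sid: _Union(iv) for sid, iv in exons.items()}
        self._warned: set[str] = set()

    def classify(self, locus) -> str:
        sid = locus.seq_id
        if sid not in self._genic:
            if sid not in self._warned:
                logger.warning(
                    "sequence %s absent from annotation; loci treated as intergenic", sid
                )
                self._warned.add(sid)
            return "intergenic"
        length = locus.end - locus.start
        genic = self._genic[sid].coverage(locus.start, locus.end)
        if genic == 0:
            return "intergenic"
        if genic < length:
            return "genic_intergenic_spanning"
        exonic = self._exonic[sid].coverage(locus.start, locus.end)
        if exonic == length:
            return "exon"
        if exonic == 0:
            return "intron"
        return "exon_intron_spanning"


def classify_region(locus, models: Sequence[GeneModel]) -> str:
    """Category of one locus; see module docstring for the decision order."""
    return RegionIndex(models).classify(locus)


def classify_regions(loci: Sequence, models: Sequence[GeneModel]) -> list[str]:
    index = RegionIndex(models)
    return [index.classify(l) for l in loci]


def tabulate_regions(loci: Sequence, models: Sequence[GeneModel]) -> dict[str, int]:
    """Counts per category plus ``total``; every locus falls in exactly one."""
    counts = {c: 0 for c in CATEGORIES}
    for cat in classify_regions(loci, models):
        counts[cat] += 1
    counts["total"] = len(loci)
    return counts


def region_table(loci: Sequence, models: Sequence[GeneModel]) -> pd.DataFrame:
    """One-row region-count table mirroring the five-category scheme."""
    counts = tabulate_regions(loci, models)
    return pd.DataFrame([counts], columns=list(CATEGORIES) + ["total"])
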