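"""Per-genome microsatellite abundance metrics and association statistics.

Frequency is the number of SSR loci per megabase of genome sequence; density
is the total SSR bases (bp) per megabase.  Both use the full assembly length
(ambiguous bases included) as the denominator, and density includes the full
span of imperfect loci.  Associations between abundance metrics and genome
size / GC content use Spearman rank correlation; group comparisons use the
unequal-variance (Welch) t test with Welch–Satterthwaite degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detect import GenomeRecord, SsrLocus

__all__ = [
    "GenomeSummary",
    "summarize_genome",
    "spearman_assoc",
    "welch_t",
    "cohort_table",
]


@dataclass
class GenomeSummary:
    genome_id: str
    genome_size: int
    gc_fraction: float
    n_ssrs: int
    ssr_bp: int
    frequency: float          # loci per Mb
    density: float            # SSR bp per Mb
    pct_perfect: float | None
    mean_len_perfect: float | None
    mean_len_imperfect: float | None
    length_class_counts: dict[int, int] = field(default_factory=dict)
    canonical_class_counts: dict[str, int] = field(default_factory=dict)


def summarize_genome(
    record: GenomeRecord | Sequence[GenomeRecord],
    loci: Sequence[SsrLocus],
    genome_id: str | None = None,
) -> GenomeSummary:
    """Abundance summary for one genome (a record or a list of scaffolds).

    Frequency = n_ssrs / (genome_size / 1e6); density = ssr_bp /
    (genome_size / 1e6).  With no loci the percentage and mean-length fields
    are reported as missing (None).
    """
    records = [record] if isinstance(record, GenomeRecord) else list(record)
    if not records:
        raise ValueError("at least one sequence record required")
    genome_size = sum(r.length for r in records)
    if genome_size == 0:
        raise ValueError("genome size is zero")
    gc_num = sum(
        r.sequence.count("G") + r.sequence.count("C") for r in records
    )
    gc_den = gc_num + sum(
        r.sequence.count("A") + r.sequence.count("T") for r in records
    )
    gc = gc_num / gc_den if gc_den else float("nan")

    n = len(loci)
    ssr_bp = sum(l.tract_length for l in loci)
    mb = genome_size / 1e6
    perfect_lens = [l.tract_length for l in loci if l.perfect]
    imperfect_lens = [l.tract_length for l in loci if not l.perfect]
    length_counts = {k: 0 for k in range(1, 7)}
    canon_counts: dict[str, int] = {}
    for l in loci:
        length_counts[l.motif_len] = length_counts.get(l.motif_len, 0) + 1
        canon_counts[l.canonical_class] = canon_counts.get(l.canonical_class, 0) + 1

    return GenomeSummary(
        genome_id=genome_id or records[0].seq_id,
        genome_size=genome_size,
        gc_fraction=gc,
        n_ssrs=n,
        ssr_bp=ssr_bp,
        frequency=n / mb,
        density=ssr_bp / mb,
        pct_perfect=(100.0 * len(perfect_lens) / n) if n else None,
        mean_len_perfect=float(np.mean(perfect_lens)) if perfect_lens else None,
        mean_len_imperfect=float(np.mean(imperfect_lens)) if imperfect_lens else None,
        length_class_counts=length_counts,
        canonical_class_counts=canon_counts,
    )


def spearman_assoc(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with two-sided p value.

    Raises ``ValueError`` for unequal lengths, n < 3, or a constant vector
    (rho is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho is undefined for a constant vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Unequal-variance t test: (t, Welch–Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    res = sps.ttest_ind(x, y, equal_var=False)
    se2x, se2y = vx / x.size, vy / y.size
    df = (se2x + se2y) ** 2 / (se2x**2 / (x.size - 1) + se2y**2 / (y.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


_COLUMNS = [
    "genome_id", "genome_size", "gc_fraction", "n_ssrs", "ssr_bp",
    "frequency", "density", "pct_perfect", "mean_len_perfect",
    "mean_len_imperfect",
] + [f"n_k{k}" for k in range(1, 7)]


def cohort_table(summaries: Sequence[GenomeSummary]) -> pd.DataFrame:
    """One row per genome, stable column order, deterministic formatting."""
    if not summaries:
        raise ValueError("at least one summary required")
    ids = [s.genome_id for s in summaries]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate genome_id(s): {dup}")
    rows = []
    for s in summaries:
        row = {
            "genome_id": s.genome_id,
            "genome_size": s.genome_size,
            "gc_fraction": round(s.gc_fraction, 6),
            "n_ssrs": s.n_ssrs,
            "ssr_bp": s.ssr_bp,
            "frequency": round(s.frequency, 6),
            "density": round(s.density, 6),
            "pct_perfect": None if s.pct_perfect is None else round(s.pct_perfect, 6),
            "mean_len_perfect": None if s.mean_len_perfect is None else round(s.mean_len_perfect, 6),
            "mean_len_imperfect": None if s.mean_len_imperfect is None else round(s.mean_len_imperfect, 6),
        }
        for k in range(1, 7):
            row[f"n_k{k}"] = s.length_class_counts.get(k, 0)
        rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS)
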