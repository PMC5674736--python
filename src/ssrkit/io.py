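"""Standard-format I/O: FASTA, GFF3, TSV tables, distance matrices.

All written tables use 1-based inclusive coordinates (the GFF3/TSV
convention); in-memory objects stay 0-based half-open.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .detect import GenomeRecord, SsrLocus
from .divergence import CompositionProfile, DistanceMatrix
from .regions import GeneModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_gff3",
    "loci_to_frame",
    "write_locus_table",
    "read_locus_table",
    "write_truth_table",
    "read_taxonomy",
    "profiles_to_frame",
    "write_profile_table",
    "read_profile_table",
    "write_distance_matrix",
]

LOCUS_COLUMNS = [
    "seq_id", "start", "end", "motif", "canonical_class", "motif_len",
    "tract_length", "n_mismatches", "perfect", "score",
]


def read_fasta(path: str | os.PathLike) -> list[GenomeRecord]:
    """Read a (possibly multi-record) FASTA file; sequences uppercased."""
    return [
        GenomeRecord(seq_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[GenomeRecord], path: str | os.PathLike) -> None:
    """Write records 60-column wrapped."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def write_gff3(
    models: Sequence[GeneModel],
    path: str | os.PathLike,
    seq_lengths: dict[str, int] | None = None,
) -> None:
    """Write gene/mRNA/exon features, 1-based inclusive, with ID/Parent links."""
    lines = ["##gff-version 3"]
    if seq_lengths:
        for sid, length in seq_lengths.items():
            lines.append(f"##sequence-region {sid} 1 {length}")
    for gm in sorted(models, key=lambda m: (m.seq_id, m.start)):
        gid, mid = gm.gene_id, f"{gm.gene_id}.t1"
        lines.append(
            f"{gm.seq_id}\tssrkit\tgene\t{gm.start + 1}\t{gm.end}\t.\t+\t.\tID={gid}"
        )
        lines.append(
            f"{gm.seq_id}\tssrkit\tmRNA\t{gm.start + 1}\t{gm.end}\t.\t+\t.\t"
            f"ID={mid};Parent={gid}"
        )
        for i, (s, e) in enumerate(gm.exons, 1):
            lines.append(
                f"{gm.seq_id}\tssrkit\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                f"ID={mid}.exon{i};Parent={mid}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def loci_to_frame(loci: Sequence[SsrLocus]) -> pd.DataFrame:
    """Locus table with 1-based inclusive start/end."""
    rows = [
        {
            "seq_id": l.seq_id,
            "start": l.start + 1,
            "end": l.end,
            "motif": l.motif,
            "canonical_class": l.canonical_class,
            "motif_len": l.motif_len,
            "tract_length": l.tract_length,
            "n_mismatches": l.n_mismatches,
            "perfect": l.perfect,
            "score": l.score,
        }
        for l in loci
    ]
    return pd.DataFrame(rows, columns=LOCUS_COLUMNS)


def write_locus_table(loci: Sequence[SsrLocus], path: str | os.PathLike) -> None:
    loci_to_frame(loci).to_csv(path, sep="\t", index=False)


def read_locus_table(path: str | os.PathLike) -> list[SsrLocus]:
    df = pd.read_csv(path, sep="\t")
    return [
        SsrLocus(
            seq_id=str(r.seq_id),
            start=int(r.start) - 1,
            end=int(r.end),
            motif=str(r.motif),
            canonical_class=str(r.canonical_class),
            motif_len=int(r.motif_len),
            tract_length=int(r.tract_length),
            n_mismatches=int(r.n_mismatches),
            perfect=bool(r.perfect),
            score=int(r.score),
        )
        for r in df.itertuples()
    ]


def write_truth_table(loci: Sequence[SsrLocus], path: str | os.PathLike) -> None:
    """Ground-truth table: seq_id, start, end (1-based), motif, class, mismatches."""
    df = loci_to_frame(loci)[
        ["seq_id", "start", "end", "motif", "canonical_class", "n_mismatches"]
    ]
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | os.PathLike) -> pd.DataFrame:
    """Taxonomy table: genome_id plus any of species/genus/family/order."""
    df = pd.read_csv(path, sep="\t")
    if "genome_id" not in df.columns:
        raise ValueError("taxonomy table must have a genome_id column")
    return df


def profiles_to_frame(profiles: Sequence[CompositionProfile]) -> pd.DataFrame:
    if not profiles:
        raise ValueError("no profiles")
    space = profiles[0].feature_space
    for p in profiles:
        if p.feature_space != space:
            raise ValueError("profiles use different feature spaces")
    rows = [
        {"genome_id": p.genome_id, **dict(zip(space, p.percentages))}
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["genome_id", *space])


def write_profile_table(
    profiles: Sequence[CompositionProfile], path: str | os.PathLike
) -> None:
    profiles_to_frame(profiles).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_profile_table(path: str | os.PathLike) -> list[CompositionProfile]:
    df = pd.read_csv(path, sep="\t")
    space = tuple(c for c in df.columns if c != "genome_id")
    out = []
    for _, row in df.iterrows():
        pct = np.array([float(row[c]) for c in space])
        pct[-1] += 100.0 - pct.sum()  # repair round-trip rounding
        out.append(
            CompositionProfile(
                genome_id=str(row["genome_id"]),
                feature_space=space,
                percentages=tuple(pct),
            )
        )
    return out


def write_distance_matrix(
    dm: DistanceMatrix, path: str | os.PathLike, style: str = "square"
) -> None:
    """Square TSV (labelled) or PHYLIP-style square matrix."""
    if style == "square":
        df = pd.DataFrame(dm.values, index=list(dm.labels), columns=list(dm.labels))
        df.to_csv(path, sep="\t", float_format="%.10g", index_label="genome_id")
    elif style == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(dm.labels)}\n")
            for lab, row in zip(dm.labels, dm.values):
                fh.write(lab + "  " + "  ".join(f"{v:.10g}" for v in row) + "\n")
    else:
        raise ValueError(f"unknown style {style!r}")
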