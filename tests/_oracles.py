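"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's vectorized/optimized code paths:
character-by-character scans, rank-then-Pearson correlation, direct formula
evaluation, and scipy's hierarchical-clustering routines as an external
check on the in-package UPGMA.
"""

from __future__ import annotations

import numpy as np


def brute_force_perfect(seq_id: str, sequence: str, min_len: int = 15):
    """Enumerate all (start, k) maximal perfect runs with primitive motifs.

    Returns tuples (start, end, motif).  N acts as a hard boundary.
    """

    def primitive(m):
        for p in range(1, len(m)):
            if len(m) % p == 0 and m[:p] * (len(m) // p) == m:
                return False
        return True

    out = []
    n = len(sequence)
    for k in range(1, 7):
        for start in range(n - k):
            if sequence[start] == "N":
                continue
            # maximal: not extendable left
            if start >= 1 and sequence[start - 1] == sequence[start + k - 1] \
                    and "N" not in sequence[start - 1 : start + k]:
                continue
            end = start + k
            if "N" in sequence[start:end]:
                continue
            while end < n and sequence[end] != "N" and sequence[end] == sequence[end - k]:
                end += 1
            if end - start >= min_len and end - start > k and primitive(sequence[start : start + k]):
                out.append((start, end, sequence[start : start + k]))
    return sorted(set(out))


def per_base_region_labels(genome_length: int, models):
    """Label every base exonic(2)/intronic(1)/intergenic(0)."""
    labels = np.zeros(genome_length, dtype=np.int8)
    for m in models:
        sub = labels[m.start : m.end]
        sub[sub == 0] = 1  # genic default: intron
    for m in models:
        for s, e in m.exons:
            labels[s:e] = 2
    # a base may be intronic in one gene and exonic in another: exon wins
    return labels


def classify_by_base_labels(locus, labels):
    seg = labels[locus.start : locus.end]
    if (seg == 0).all():
        return "intergenic"
    if (seg == 0).any():
        return "genic_intergenic_spanning"
    if (seg == 2).all():
        return "exon"
    if (seg == 1).all():
        return "intron"
    return "exon_intron_spanning"


def spearman_brute(x, y):
    """Average ranks, then Pearson on the ranks (tie-corrected)."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(v.size)
        i = 0
        sorted_v = v[order]
        while i < v.size:
            j = i
            while j + 1 < v.size and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def welch_brute(x, y):
    """Direct Welch statistic and Welch–Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    t = (x.mean() - y.mean()) / np.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return float(t), float(df)


def scipy_upgma_cophenetic(labels, matrix):
    """Cophenetic distances of scipy's average-linkage tree, as a square
    matrix in the sorted-label order used by UltrametricTree.cophenetic()."""
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    z = linkage(squareform(matrix), method="average")
    coph = squareform(cophenet(z))
    order = np.argsort(labels)
    return coph[np.ix_(order, order)]
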