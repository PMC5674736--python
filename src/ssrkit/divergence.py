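"""Composition profiles, symmetrized Kullback–Leibler divergence, UPGMA.

Each genome is reduced to a percentage vector over a feature space — either
the motif-length classes (di- through hexanucleotide by default) or the
canonical motif classes of a single length k.  Pairwise dissimilarity between
genomes is the symmetrized Kullback–Leibler divergence (J-divergence)

    J(p, q) = Σ_x p(x) ln(p(x)/q(x)) + Σ_x q(x) ln(q(x)/p(x))

in nats, with p and q as proportions.  J is symmetric, non-negative and zero
iff p = q, but it is not a metric (no triangle inequality).  Genomes are then
clustered by UPGMA (average linkage over original leaf pairs), merging at
height d/2, which yields a rooted ultrametric tree.

Many genomes lack whole motif classes and KL is undefined at zeros, so
profiles are smoothed with a pseudocount (default 0.5 counts per feature)
before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .motifs import enumerate_classes

__all__ = [
    "CompositionProfile",
    "DistanceMatrix",
    "TreeNode",
    "UltrametricTree",
    "length_feature_space",
    "canonical_feature_space",
    "build_profile",
    "sym_kl",
    "pairwise_matrix",
    "upgma",
    "write_newick",
]

_LENGTH_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


def length_feature_space(ks: Sequence[int] = (2, 3, 4, 5, 6)) -> tuple[str, ...]:
    """Feature names for motif-length classes (default di..hexa)."""
    if any(k not in _LENGTH_NAMES for k in ks):
        raise ValueError("motif lengths must be in 1..6")
    return tuple(_LENGTH_NAMES[k] for k in ks)


def canonical_feature_space(k: int) -> tuple[str, ...]:
    """Feature names: canonical motif classes of one length k."""
    return tuple(cls.canonical for cls in enumerate_classes(k))


@dataclass(frozen=True)
class CompositionProfile:
    """Percentage vector over a feature space for one genome; sums to 100."""

    genome_id: str
    feature_space: tuple[str, ...]
    percentages: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.percentages, dtype=float)
        if len(self.feature_space) != p.size:
            raise ValueError("feature_space and percentages differ in length")
        if (p < 0).any():
            raise ValueError("percentages must be non-negative")
        if abs(p.sum() - 100.0) > 1e-9:
            raise ValueError(f"percentages must sum to 100, got {p.sum()!r}")

    @property
    def proportions(self) -> np.ndarray:
        return np.asarray(self.percentages, dtype=float) / 100.0


def build_profile(
    loci: Sequence,
    feature_space: tuple[str, ...] | None = None,
    pseudocount: float = 0.5,
    genome_id: str = "",
) -> CompositionProfile:
    """Count loci per feature, add a pseudocount, normalize to percentages.

    With the default length feature space a locus contributes to the feature
    of its motif length; with a canonical space (all features length k) a
    locus contributes to its canonical class, and loci of other motif lengths
    are ignored.
    """
    feature_space = feature_space or length_feature_space()
    name_to_idx = {f: i for i, f in enumerate(feature_space)}
    length_to_idx = {
        k: name_to_idx[name]
        for k, name in _LENGTH_NAMES.items()
        if name in name_to_idx
    }
    counts = np.zeros(len(feature_space), dtype=float)
    for l in loci:
        if l.canonical_class in name_to_idx:
            counts[name_to_idx[l.canonical_class]] += 1
        elif l.motif_len in length_to_idx:
            counts[length_to_idx[l.motif_len]] += 1
    counts += pseudocount
    total = counts.sum()
    if total == 0:
        raise ValueError("no loci in the feature space and pseudocount is 0")
    pct = counts / total * 100.0
    pct[-1] += 100.0 - pct.sum()  # absorb rounding so the invariant is exact
    gid = genome_id or (loci[0].seq_id if len(loci) else "")
    return CompositionProfile(
        genome_id=gid, feature_space=tuple(feature_space), percentages=tuple(pct)
    )


def sym_kl(p: CompositionProfile, q: CompositionProfile) -> float:
    """Symmetrized Kullback–Leibler divergence (nats) between two profiles."""
    if p.feature_space != q.feature_space:
        raise ValueError("profiles use different feature spaces")
    a, b = p.proportions, q.proportions
    if (a == 0).any() or (b == 0).any():
        raise ValueError(
            "zero entry in profile; build profiles with a positive pseudocount"
        )
    return float(np.sum(a * np.log(a / b)) + np.sum(b * np.log(b / a)))


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.isfinite(v).all():
            raise ValueError("distances must be finite")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def pairwise_matrix(profiles: Sequence[CompositionProfile]) -> DistanceMatrix:
    """Symmetric matrix of pairwise J-divergences."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    ids = [p.genome_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids among profiles")
    n = len(profiles)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = sym_kl(profiles[i], profiles[j])
    return DistanceMatrix(labels=tuple(ids), values=m)


@dataclass(frozen=True)
class TreeNode:
    """Node of a rooted ultrametric tree: leaves at height 0."""

    height: float
    label: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out


@dataclass(frozen=True)
class UltrametricTree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes (root included)."""
        out: list[frozenset[str]] = []

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            s = frozenset().union(*(walk(c) for c in node.children))
            out.append(s)
            return s

        walk(self.root)
        return out

    def is_monophyletic(self, labels: Sequence[str]) -> bool:
        """True if some clade's leaf set equals ``labels`` exactly."""
        target = frozenset(labels)
        if len(target) == 1:
            return target <= frozenset(self.leaf_names())
        return target in set(self.clades())

    def cophenetic(self) -> tuple[list[str], np.ndarray]:
        """Leaf labels and the matrix of 2 × (height of the lowest common
        ancestor) — the tree's ultrametric distances."""
        labels = sorted(self.leaf_names())
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2 * node.height
            return [l for g in groups for l in g]

        walk(self.root)
        return labels, d

    def newick(self) -> str:
        return write_newick(self)


def upgma(matrix: DistanceMatrix) -> UltrametricTree:
    """Average-linkage agglomerative clustering into an ultrametric tree.

    At each step the pair of clusters with the smallest distance merges at
    height d/2; the new cluster's distance to any other is the size-weighted
    mean (equivalently the arithmetic mean over all original leaf pairs).
    Ties are broken by the lexicographically smallest pair of cluster keys,
    a cluster's key being its smallest leaf label, so the output is
    deterministic.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=lab) for i, lab in enumerate(matrix.labels)
    }
    keys: dict[int, str] = {i: lab for i, lab in enumerate(matrix.labels)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(matrix.values[i, j])
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = min(
            (
                (dist[(min(i, j), max(i, j))], tuple(sorted((keys[i], keys[j]))), (i, j))
                for i in active
                for j in active
                if i < j
            ),
            key=lambda t: (t[0], t[1]),
        )
        d, _, (i, j) = best
        h = d / 2.0
        ci, cj = nodes[i], nodes[j]
        children = tuple(sorted((ci, cj), key=lambda c: min(c.leaf_names())))
        new = TreeNode(height=h, children=children)
        new_id = next_id
        next_id += 1
        active -= {i, j}
        for m in active:
            dim = dist[(min(i, m), max(i, m))]
            djm = dist[(min(j, m), max(j, m))]
            dist[(min(new_id, m), max(new_id, m))] = (
                sizes[i] * dim + sizes[j] * djm
            ) / (sizes[i] + sizes[j])
        nodes[new_id] = new
        keys[new_id] = min(keys[i], keys[j])
        sizes[new_id] = sizes[i] + sizes[j]
        active.add(new_id)
    return UltrametricTree(root=nodes[next_id - 1])


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: UltrametricTree) -> str:
    """Newick text with branch lengths = parent height − child height."""

    def render(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.label
        else:
            body = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{_fmt(parent_height - node.height)}"

    return render(tree.root, None) + ";"
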