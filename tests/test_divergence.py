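"""Composition profiles, J-divergence, UPGMA against independent oracles."""

import numpy as np
import pytest
from scipy.stats import entropy

from ssrkit.detect import SsrLocus
from ssrkit.divergence import (
    CompositionProfile,
    DistanceMatrix,
    build_profile,
    canonical_feature_space,
    length_feature_space,
    pairwise_matrix,
    sym_kl,
    upgma,
    write_newick,
)

from _oracles import scipy_upgma_cophenetic


def _profile(gid, pcts, space=("a", "b")):
    return CompositionProfile(genome_id=gid, feature_space=space, percentages=tuple(pcts))


def _loci(n, motif, seq_id="g"):
    return [SsrLocus.make(seq_id, i * 100, i * 100 + 20, motif, 0) for i in range(n)]


class TestBuildProfile:
    def test_counts_normalized_to_percentages(self):
        loci = _loci(50, "AT") + _loci(50, "AG")
        p = build_profile(loci, canonical_feature_space(2), pseudocount=0)
        d = dict(zip(p.feature_space, p.percentages))
        assert d["AT"] == pytest.approx(50.0)
        assert d["AG"] == pytest.approx(50.0)
        assert d["AC"] == 0 and d["CG"] == 0

    def test_pseudocount_makes_all_features_positive(self):
        p = build_profile(_loci(10, "AT"), length_feature_space(), pseudocount=0.5)
        assert min(p.percentages) > 0

    def test_scale_invariance(self):
        a = build_profile(_loci(10, "AT") + _loci(30, "ACG"), pseudocount=0)
        b = build_profile(_loci(20, "AT") + _loci(60, "ACG"), pseudocount=0)
        assert a.percentages == pytest.approx(b.percentages)

    def test_empty_without_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            build_profile([], length_feature_space(), pseudocount=0)

    def test_sum_is_exactly_100(self, rng):
        for _ in range(20):
            loci = _loci(int(rng.integers(1, 40)), "AT") + _loci(
                int(rng.integers(1, 40)), "AAC"
            )
            p = build_profile(loci, pseudocount=0.5)
            assert sum(p.percentages) == pytest.approx(100.0, abs=1e-9)


class TestSymKl:
    def test_identical_profiles_zero(self):
        p = _profile("x", (60.0, 40.0))
        assert sym_kl(p, _profile("y", (60.0, 40.0))) == 0.0

    def test_worked_value(self):
        p = _profile("p", (50.0, 50.0))
        q = _profile("q", (90.0, 10.0))
        # direct term-by-term: 0.5 ln(25/9) + 0.9 ln 1.8 + 0.1 ln 0.2
        assert sym_kl(p, q) == pytest.approx(0.8789, abs=1e-4)

    def test_symmetry_and_nonnegativity(self, rng):
        space = ("a", "b", "c", "d")
        for _ in range(50):
            x = rng.dirichlet(np.ones(4)) * 100
            y = rng.dirichlet(np.ones(4)) * 100
            x[-1] += 100 - x.sum()
            y[-1] += 100 - y.sum()
            p, q = _profile("p", x, space), _profile("q", y, space)
            d = sym_kl(p, q)
            assert d >= 0
            assert d == pytest.approx(sym_kl(q, p))
            # independent check via scipy's KL (relative entropy)
            assert d == pytest.approx(
                entropy(x / 100, y / 100) + entropy(y / 100, x / 100), abs=1e-10
            )

    def test_mismatched_spaces_rejected(self):
        with pytest.raises(ValueError):
            sym_kl(_profile("p", (50.0, 50.0)), _profile("q", (50.0, 50.0), ("x", "y")))

    def test_zero_entry_directs_to_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            sym_kl(_profile("p", (100.0, 0.0)), _profile("q", (50.0, 50.0)))


class TestPairwiseMatrix:
    def test_identical_profiles_zero_matrix(self):
        m = pairwise_matrix([_profile("a", (50.0, 50.0)), _profile("b", (50.0, 50.0))])
        assert np.allclose(m.values, 0)

    def test_entries_match_elementwise_sym_kl(self, rng):
        space = ("a", "b", "c")
        profs = []
        for i in range(5):
            x = rng.dirichlet(np.ones(3)) * 100
            x[-1] += 100 - x.sum()
            profs.append(_profile(f"g{i}", x, space))
        m = pairwise_matrix(profs)
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else sym_kl(profs[i], profs[j])
                assert m.values[i, j] == pytest.approx(expected)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            pairwise_matrix([_profile("a", (50.0, 50.0))] * 2)


class TestUpgma:
    def test_two_taxa(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = upgma(dm)
        assert tree.root.height == pytest.approx(1.5)
        assert sorted(tree.leaf_names()) == ["A", "B"]

    def test_three_taxa_hand_example(self):
        dm = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]]),
        )
        tree = upgma(dm)
        heights = sorted(
            {round(c, 10) for c in _internal_heights(tree.root)}
        )
        assert heights == [1.0, 4.0]
        assert tree.is_monophyletic(["A", "B"])

    def test_matches_scipy_average_linkage(self, rng):
        for _ in range(100):
            n = 8
            x = rng.random((n, 3))
            m = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))  # tie-free
            labels = tuple(f"t{i}" for i in range(n))
            tree = upgma(DistanceMatrix(labels, m))
            labs, coph = tree.cophenetic()
            oracle = scipy_upgma_cophenetic(list(labels), m)
            assert np.allclose(coph, oracle, atol=1e-10)

    def test_reconstructs_ultrametric_input_exactly(self, rng):
        for _ in range(20):
            tree0 = _random_ultrametric(rng, 7)
            labs, d = tree0.cophenetic()
            tree1 = upgma(DistanceMatrix(tuple(labs), d))
            labs1, d1 = tree1.cophenetic()
            assert labs == labs1
            assert np.allclose(d, d1, atol=1e-9)

    def test_output_is_ultrametric(self, rng):
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = upgma(DistanceMatrix(tuple("ABCDEF"), m))
        depths = _leaf_depths(tree.root, tree.root.height)
        assert max(depths) - min(depths) < 1e-9

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestNewick:
    def test_two_leaf_example(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert write_newick(upgma(dm)) == "(A:1,B:1);"

    def test_round_trip_through_skbio(self, rng):
        import io as _io

        import skbio

        m = rng.random((5, 5))
        m = (m + m.T) / 2 + 0.1
        np.fill_diagonal(m, 0)
        tree = upgma(DistanceMatrix(tuple("ABCDE"), m))
        text = write_newick(tree)
        st = skbio.TreeNode.read(_io.StringIO(text))
        # same leaves, same root-to-tip distances (ultrametric preserved)
        tips = {t.name: st.distance(t) for t in st.tips()}
        assert set(tips) == set("ABCDE")
        assert max(tips.values()) - min(tips.values()) < 1e-9
        assert max(tips.values()) == pytest.approx(tree.root.height)


def _internal_heights(node):
    if node.is_leaf:
        return []
    out = [node.height]
    for c in node.children:
        out.extend(_internal_heights(c))
    return out


def _leaf_depths(node, root_height):
    if node.is_leaf:
        return [root_height - node.height]
    out = []
    for c in node.children:
        out.extend(_leaf_depths(c, root_height))
    return out


def _random_ultrametric(rng, n):
    """Random ultrametric tree via UPGMA on random data, then jitter heights."""
    from ssrkit.divergence import TreeNode, UltrametricTree

    nodes = [TreeNode(height=0.0, label=f"t{i}") for i in range(n)]
    height = 0.0
    while len(nodes) > 1:
        height += float(rng.random()) + 0.1
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(height=height, children=(nodes[i], nodes[j]))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    return UltrametricTree(root=nodes[0])
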