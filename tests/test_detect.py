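"""Detector unit and property tests: perfect runs, seed-and-extend, overlaps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrkit.detect import (
    DetectionParams,
    GenomeRecord,
    SsrLocus,
    find_all_ssrs,
    find_imperfect_ssrs,
    find_perfect_ssrs,
    resolve_overlaps,
    split_on_ambiguity,
)
from ssrkit.motifs import reverse_complement

from _oracles import brute_force_perfect

dna = st.text(alphabet="ACGT", min_size=0, max_size=400)
dna_n = st.text(alphabet="ACGTN", min_size=0, max_size=400)


def _rec(seq):
    return GenomeRecord("s", seq)


class TestSplitOnAmbiguity:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGTNNACGT", [(0, "ACGT"), (6, "ACGT")]),
            ("ACGT", [(0, "ACGT")]),
            ("NNNN", []),
            ("", []),
            ("NACGTN", [(1, "ACGT")]),
        ],
    )
    def test_examples(self, seq, expected):
        assert split_on_ambiguity(seq) == expected

    @given(dna_n)
    def test_concatenation_recovers_sequence_without_ns(self, seq):
        segments = split_on_ambiguity(seq)
        assert "".join(s for _, s in segments) == seq.replace("N", "")
        for off, sub in segments:
            assert seq[off : off + len(sub)] == sub


class TestPerfectDetection:
    def test_minimal_dinucleotide_above_threshold(self):
        loci = find_perfect_ssrs(_rec("AT" * 8))
        assert len(loci) == 1
        l = loci[0]
        assert (l.start, l.end, l.motif, l.canonical_class, l.perfect) == (
            0, 16, "AT", "AT", True,
        )

    def test_fourteen_bp_below_threshold(self):
        assert find_perfect_ssrs(_rec("AT" * 7)) == []

    def test_embedded_trinucleotide_tract(self, rng):
        left = "".join(rng.choice(list("ACGT"), size=50))
        right = "".join(rng.choice(list("ACGT"), size=50))
        # flanks must not extend the planted period-3 pattern by chance
        left = left[:-1] + ("T" if left[-1] == "G" else left[-1])
        right = ("T" if right[0] == "A" else right[0]) + right[1:]
        seq = left + "ACG" * 6 + right
        expected = brute_force_perfect("s", seq)
        got = [(l.start, l.end, l.motif) for l in find_perfect_ssrs(_rec(seq))]
        assert got == expected
        assert (50, 68, "ACG") in expected

    def test_empty_sequence(self):
        assert find_perfect_ssrs(_rec("")) == []

    def test_invalid_character_named_in_error(self):
        with pytest.raises(ValueError, match="X"):
            find_perfect_ssrs(_rec("ACGTX" * 10))

    def test_no_locus_spans_an_n(self):
        seq = "AT" * 10 + "N" + "AT" * 10
        loci = find_perfect_ssrs(_rec(seq))
        assert [(l.start, l.end) for l in loci] == [(0, 20), (21, 41)]

    @given(dna_n)
    @settings(max_examples=200)
    def test_matches_bruteforce_on_random_sequences(self, seq):
        got = sorted((l.start, l.end, l.motif) for l in find_perfect_ssrs(_rec(seq)))
        assert got == brute_force_perfect("s", seq)

    @given(dna)
    def test_reverse_complement_covariance(self, seq):
        """Mirrored coordinates, same canonical classes, on the rev-comp."""
        fwd = find_perfect_ssrs(_rec(seq))
        rev = find_perfect_ssrs(_rec(reverse_complement(seq)))
        n = len(seq)
        fwd_set = sorted((n - l.end, n - l.start, l.canonical_class) for l in fwd)
        rev_set = sorted((l.start, l.end, l.canonical_class) for l in rev)
        assert fwd_set == rev_set


class TestImperfectDetection:
    def test_single_substitution_counted(self):
        seq = list("AT" * 10)
        seq[9] = "G"  # interior substitution
        loci = find_imperfect_ssrs(_rec("".join(seq)))
        assert len(loci) == 1
        l = loci[0]
        assert (l.start, l.end, l.n_mismatches, l.perfect) == (0, 20, 1, False)

    def test_perfect_tract_consistent_with_perfect_finder(self):
        seq = "ACG" * 7
        [imp] = find_imperfect_ssrs(_rec(seq))
        [per] = find_perfect_ssrs(_rec(seq))
        assert (imp.start, imp.end, imp.motif, imp.n_mismatches) == (
            per.start, per.end, per.motif, 0,
        )

    def test_extension_stops_near_planted_boundary(self, rng):
        tract = "AAAT" * 4
        # non-repetitive tail: maximal-score trimming must stop within
        # max_score_drop bases of the tract end
        tail = "GCGTCAGTCTGACGATGCAGTCGATCGTAG"
        loci = find_imperfect_ssrs(_rec(tract + tail), DetectionParams())
        assert loci, "seeded tract must be found"
        l = max(loci, key=lambda x: x.score)
        assert l.start == 0
        assert abs(l.end - len(tract)) <= DetectionParams().max_score_drop

    def test_mismatch_count_matches_alignment_oracle(self, rng):
        """Planted substitutions are recovered by comparing against the pure
        periodic sequence."""
        for k, motif in [(2, "AT"), (3, "ACG"), (4, "AATC")]:
            copies = 12
            tract = list(motif * copies)
            pos = 3 * k + 1
            tract[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tract[pos]]
            seq = "".join(tract)
            pure = (motif * copies)[: len(seq)]
            expected_mm = sum(a != b for a, b in zip(seq, pure))
            loci = find_imperfect_ssrs(_rec(seq))
            l = max(loci, key=lambda x: x.score)
            assert l.n_mismatches == expected_mm == 1

    def test_score_formula(self):
        seq = list("AT" * 12)
        seq[11] = "C"
        [l] = find_imperfect_ssrs(_rec("".join(seq)))
        assert l.score == (l.tract_length - l.n_mismatches) - 5 * l.n_mismatches


class TestResolveOverlaps:
    def _locus(self, start, end, motif, nm=0):
        return SsrLocus.make("s", start, end, motif, nm)

    def test_non_overlapping_unchanged(self):
        loci = [self._locus(0, 20, "AT"), self._locus(50, 70, "ACG")]
        assert resolve_overlaps(loci) == sorted(loci, key=lambda l: l.start)

    def test_higher_score_wins(self):
        a = self._locus(0, 20, "AT")        # score 20
        b = self._locus(10, 28, "ACG")      # score 18
        assert resolve_overlaps([a, b]) == [a]

    def test_tie_prefers_smaller_motif(self):
        a = self._locus(0, 16, "A")
        b = self._locus(0, 16, "AT")
        assert resolve_overlaps([a, b]) == [a]

    def test_mononucleotide_run_reported_once(self):
        loci = find_all_ssrs(_rec("A" * 16))
        assert len(loci) == 1
        assert loci[0].motif == "A"


class TestDetectionParams:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            DetectionParams(min_tract_length=0)

    def test_rejects_bad_motif_lengths(self):
        with pytest.raises(ValueError):
            DetectionParams(motif_lengths=(0, 7))

    def test_min_tract_vs_seed(self):
        with pytest.raises(ValueError):
            DetectionParams(min_tract_length=6, seed_min_length=8)


def test_every_locus_respects_invariants(small_genome):
    record, _ = small_genome
    params = DetectionParams()
    for l in find_all_ssrs(record, params):
        assert l.tract_length == l.end - l.start >= params.min_tract_length
        assert l.perfect == (l.n_mismatches == 0)
        assert 1 <= l.motif_len <= 6
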