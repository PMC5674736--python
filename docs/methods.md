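# Methods

## Problem and model

`ssrkit` treats a genome's microsatellite complement as a point process of
repeat tracts plus a composition vector over motif classes, and implements
four linked computations: tract detection, motif-class algebra, regional
annotation, and composition-divergence clustering. The sections below give
the operational definitions, the tunable parameters, what the synthetic
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Detection

A perfect SSR is a maximal run in which `s[i] == s[i-k]` for a primitive
k-mer, k ∈ {1..6}, with run length ≥ `min_tract_length` (15 bp). Runs are
found per period with a vectorized shifted-equality scan; a maximal run
whose leading k-mer is non-primitive (e.g. "AA" at period 2 inside a poly-A
run) is covered at the smaller period and not reported at k.

Imperfect SSRs use seed-and-extend. A seed is a perfect run of at least
`seed_min_copies` (3) copies and `seed_min_length` (8) bp. Extension in
each direction compares every base to the periodic expectation *anchored at
the seed* (so the pattern cannot drift across mismatches), scores +1 per
match and −`mismatch_penalty` (5) per mismatch, stops once the running
score falls more than `max_score_drop` (5) below its running maximum, and
trims the tract back to the maximal-score position. Mismatches are counted
by comparing the reported tract to the pure periodic sequence in the seed's
phase. With penalty = drop = 5, one isolated mismatch is always crossed,
while two mismatches closer than five matching bases terminate extension —
this is what makes sparse-mismatch tracts recoverable with exact counts.

The unified call set is the union of perfect and seeded-imperfect
candidates, made non-redundant by `resolve_overlaps`: higher score wins;
ties prefer the smaller motif length, then the smaller start. Perfect and
imperfect loci thus partition one call set rather than coming from two
different detectors.

Parameter summary (all configurable via `DetectionParams`):

| parameter | default | unit | role |
|---|---|---|---|
| `min_tract_length` | 15 | bp | defining tract-length threshold |
| `seed_min_copies` | 3 | copies | minimum perfect seed, in copies |
| `seed_min_length` | 8 | bp | minimum perfect seed, in bases |
| `mismatch_penalty` | 5 | score | cost per mismatch during extension |
| `max_score_drop` | 5 | score | x-drop termination threshold |

Ambiguity: N runs are hard boundaries. Deleting Ns would shift every
downstream coordinate out of register with the annotation, so segments
between N runs are scanned independently and all coordinates stay in the
original frame. Consequently the effective denominator for frequency and
density is the full assembly length, N included.

Known limitation: when a non-repetitive prefix of one period adjoins a
repeat of another period sharing its first bases (poly-A directly followed
by an A-starting dinucleotide tract), the longer-period maximal run starts
with a non-primitive k-mer and is dropped at that period, so such a
boundary case can mask the shorter tract. The synthetic generator's flank
rules make this configuration impossible on planted truth; on real genomes
it affects only tracts butted directly against a compatible homopolymer.

## Motif classes

Classes are orbits of primitive k-mers under cyclic rotation and reverse
complement, named by the lexicographically smallest member (A < C < G < T):
2 mononucleotide classes (A, C), 4 dinucleotide (AC, AG, AT, CG), 10
trinucleotide, and so on; the enumeration is computed once per k and
cached, never hard-coded beyond the k ≤ 3 spot checks in the tests.

Perfection schemes: the default `any_mismatch` rule calls a tract imperfect
iff it has ≥ 1 mismatch. A `length_stratified` variant (≥ 30 bp with 1–3
mismatches, or ≤ 30 bp with ≥ 3) is kept for sensitivity analysis; tracts
matching neither stratum fall back to the any-mismatch rule, which makes
the two schemes extensionally equivalent — the variant exists so the
stratified criterion can be tightened in one place if ever needed.

## Regions

Gene models come from GFF3 via gffutils; exons of all transcripts of a gene
are unioned, introns are the within-span complement. Classification order:
overlap with any gene span but extension outside all spans →
genic–intergenic spanning; fully genic crossing exon and intron bases →
exon–intron spanning; otherwise exon, intron, or intergenic. A base is
exonic if exonic in any gene; strand is ignored. Overlap means ≥ 1 shared
base, all arithmetic half-open. Loci on sequences absent from the
annotation are intergenic (with a logged warning). The five categories are
exhaustive and mutually exclusive, so category counts always sum to the
locus total; the tests enforce this identity and check the interval logic
against an exhaustive per-base labeling oracle.

## Summaries and statistics

Frequency = loci per Mb; density = SSR bp per Mb, including the full span
of imperfect tracts (mismatched bases are part of the tract). GC content is
computed over unambiguous bases. Spearman correlation (tie-corrected) and
the Welch t test (with Welch–Satterthwaite df) are thin wrappers over
scipy, validated in the tests against direct rank-and-Pearson and
direct-formula implementations to 1e-10. Constant vectors and
zero-variance pairs raise rather than returning NaN.

## Composition divergence and clustering

Profiles are percentage vectors over either the motif-length classes di-
through hexanucleotide (the default headline space; mononucleotides are
excluded there because single-base composition is dominated by genome GC
rather than repeat biology, and single-k canonical spaces are available
separately) or the canonical classes of one k. Counts get a pseudocount
(default 0.5 per feature) before normalization, because KL divergence is
undefined at zeros and real genomes routinely lack whole classes.

The dissimilarity is the J-divergence J(p,q) = KL(p‖q) + KL(q‖p) in nats.
Natural log and sum-symmetrization are conventions only: UPGMA topology is
invariant to the log base and to the constant factor between sum and mean.
J is symmetric, non-negative and zero iff p = q, but satisfies no triangle
inequality; it is used strictly as a clustering dissimilarity, not a
metric.

UPGMA merges the closest pair at height d/2 and updates distances as
size-weighted means (the arithmetic mean over all original leaf pairs).
Ties are broken by the lexicographically smallest pair of cluster keys (a
cluster's key is its smallest leaf label), making the output deterministic.
The implementation is the straightforward O(n³) algorithm — cohort sizes
here are tens to low hundreds of genomes — and is cross-checked in the
tests against scipy's average-linkage cophenetic distances on random
matrices and against exact reconstruction from ultrametric inputs. Newick
output carries branch lengths parent-height − child-height, so root-to-tip
distances all equal the root height.

## Synthetic genomes

The generator exists to give every stage ground truth, and its construction
rules are chosen to make that truth unambiguous:

- Background is i.i.d. with P(G)+P(C) = `gc_fraction` (default 0.35,
  AT-rich as typical for insect assemblies). After planting, any maximal
  perfect run ≥ 15 bp not fully inside a planted tract triggers
  regeneration of its background bases, iterated to convergence — so the
  background contains no incidental SSR calls.
- Planted tracts are separated by ≥ 20 bp, and the single base on each
  side of a tract is forced to differ from the periodic continuation, so
  the maximal run equals the planted interval exactly.
- Mismatches are substitutions, kept ≥ max(k, 6) bp from tract ends,
  pairwise separated by ≥ max(3k, 8)+1 bp, with at least one clean run of
  max(3k, 8) bp (a guaranteed seed). Planted perfect tracts target
  16–30 bp and imperfect tracts 28–72 bp with 1–3 mismatches — the length
  and sparsity regimes reported for real perfect vs imperfect
  microsatellites, where mismatch content is on the order of 1–2% of tract
  bases.
- Gene models are single-transcript, 1–5 exons, introns ≥ 50 bp,
  non-overlapping — sufficient for the five-category region scheme.

Cohorts draw per-genome class proportions from
Dirichlet(concentration × family mean) and realize them as multinomial
counts (`ssrs_per_genome`, default 150; concentration default 200, i.e.
within-family composition noise of a few percentage points per class;
`concentration = inf` reproduces the family mean exactly). Genomes are laid
out as plants separated by 25–150 bp gaps, giving compact (tens of kb)
genomes whose composition, not size, carries the signal.

What the generator does **not** emulate: realistic base composition beyond
a single GC knob, transposable elements and SSR–repeat associations,
indel-type imperfections (substitutions only), compound/adjacent SSRs, and
assembly artifacts. Passing the recovery tests therefore shows the
detector is correct w.r.t. the operational tract definition, not that its
counts would match any particular external tool on real genomes, where
parameter conventions (especially seed and penalty choices) dominate the
differences between published detectors.

## Problem sizes and determinism

The test suite runs recovery on twenty ~1 Mb genomes (~300 plants each),
oracle equivalence on 200 random ≤ 2 kb sequences, region oracles on fifty
100 kb annotated genomes, and twenty clustering replicates of 4 families ×
5 genomes (plus twenty negative-control replicates with identical family
means, where all-family monophyly collapses to near zero). The acceptance
script uses ten 1-Mb genomes and ten clustering replicates. All randomness
flows through explicit `numpy.random.default_rng` seeds; identical seeds
give byte-identical sequences, truth tables and pipeline artifacts (the
run log deliberately records parameters and counts but no timestamps, so
reruns are checksum-identical).

## Degenerate inputs and tie-breaks, collected

- Empty sequence or all-N sequence: empty locus list.
- Invalid characters: error naming the symbol.
- Zero loci: frequency/density 0; percent-perfect and mean lengths are
  missing (None), not 0.
- Constant vectors (Spearman) and zero-variance pairs (Welch): errors.
- Zero profile entries passed to J-divergence: error directing the caller
  to a positive pseudocount.
- Overlap resolution and UPGMA tie-breaks as described above; both are
  deterministic by construction.
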