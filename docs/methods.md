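# Methods

## Counting model

The unit of analysis is the (read, KO) annotation.  Duplicate hits of one
read to the same KO are collapsed to a single record keeping the smallest
e-value (ties: first occurrence), so each read contributes at most once
per KO; a read annotated to two *different* KOs contributes to both
(default `per_ko` counting).  This is the least destructive reading of
"counting KO appearances in reads"; a `best_hit` mode restricting each
read to its single strongest annotation is provided for sensitivity
analyses.  Similarity clusters (`aa90_*` records with a separate
cluster-to-read mapping) are fanned out to their member reads before
filtering, each member inheriting the cluster's e-value and identity.

Quality filters use strict inequalities: e-value < 1e-5 always, and
identity > 75 optionally (intended for short-read paired designs whose
annotations are less reliable).  A record at exactly the threshold is
removed.

## Enrichment tests

Superset design (viral reads are a subset of the reference): the
hypergeometric upper tail P(X ≥ k) with population N (reference
annotation total), K successes (reference annotations of the KO), n draws
(viral annotation total).  The printed form of the test statistic is a
point mass; a point mass is not a usable over-representation p-value, so
calling uses the tail, with the point-mass mode retained
(`hypergeom_pmf`) for fidelity checks.  Paired design (virome vs
microbiome): one-sided Fisher exact test, which is the same tail
conditioned on the 2×2 margins — an identity the test suite verifies
against an independent hypergeometric route.

The calling threshold is a raw P < 1e-4 with no multiple-testing
correction, matching standard practice for this analysis; BH adjustment
is available behind `adjust="benjamini-hochberg"`.  Tails are evaluated
through scipy's log-gamma machinery; an exact rational path
(`hypergeom_upper_tail_exact`) exists for small populations and anchors
the unit tests (agreement to 1e-12 absolute for N ≤ 30).

## Pathway enrichment score

ES = N · Σ −log10(P_n) / T over the pathway's enriched member KOs.  The
summand is read as −log10 P_n (sum of negative logs), not 1 − log10 P_n:
cross-row consistency of the published score table identifies a single
per-KO weight reusable across rows only under the former reading, and the
acceptance suite reconstructs eight rows of that table to ≤ 1e-5 relative
error on this basis.  A caveat worth recording: back-solved weights imply
some per-KO p-values around 6e-3, which is weaker than the 1e-4 calling
threshold; the package nevertheless treats the P_n entering the score as
the same quantity as the calling p-value, since nothing else is
identifiable from the published numbers.  KOs shared between pathways
contribute their full weight to every pathway containing them.  P-values
are floored at 1e-300 (configurable) before taking logs; an exact zero
without a floor is a hard error.

## Global metabolism network

Nodes are pathways; an undirected, unweighted edge {A, B} exists iff
products(A) ∩ substrates(B) ≠ ∅ or products(B) ∩ substrates(A) ≠ ∅.  No
compound is excluded by default — a currency-metabolite exclusion list is
accepted but empty, since the upstream analysis defines none.  Degree
ranking breaks ties lexicographically by pathway id (deterministic);
because ties can materially affect prefix statistics, a
permutation-sampling validation mode (`mhg_pvalue_sampled`) exists for
checking any particular ranking.

The mHG statistic of the ranked enriched-membership vector is the minimum
over prefix lengths of the hypergeometric upper tail.  Its p-value is
computed exactly: all prefix tails are evaluated as exact rationals
(integer binomials), the cells of the (rank × hits) lattice whose tail is
≤ the observed minimum are marked absorbing, and the surviving
lattice paths are counted by dynamic programming; p = 1 − good/C(L,B).
Exact arithmetic removes any tolerance issue in the ≤ comparisons, which
is what makes the DP provably equal to exhaustive permutation enumeration
(verified for every vector of length ≤ 10, plus the standard sandwich
statistic ≤ p ≤ statistic·L on random vectors).

Distance analysis: shells are BFS distances from the target pathway set
merged into a single source (distance to the nearest target), the reading
consistent with treating e.g. purine + pyrimidine metabolism as one hub;
a `max` mode (farthest per-target distance) is provided since the merged
reading is not the only defensible one.  Targets sit at distance 0 and
are excluded from shells; unreachable nodes are reported separately and
excluded from shell statistics.  Per-shell enrichment is the
hypergeometric tail of the shell's enriched count against all
shell-assigned nodes.  The distance comparison uses Welch's t-test by
default (pooled-variance optional); the degree comparison uses the
two-sided Mann–Whitney test with tie correction, reporting scipy's U
convention (pairs won by the enriched group, ties half).

## Metabolic motifs

A motif is a simple chain of consecutive reactions (the product of one is
the substrate of the next) with length ≥ 4, ≥ 3 reactions promoted by
enriched KOs, and at most 1 not.  Only *maximal* chains are reported — a
chain extendable at either end without breaking simplicity or the
non-enriched budget is suppressed — to avoid combinatorial sub-chain
duplication; `maximal=False` enumerates all qualifying sub-chains.
Edges are traversed as written by default; `direction="both"` walks
reactions in either orientation (each reaction still used at most once
per chain) for reversible-reaction analyses.

Scoring: p is the fraction of the pathway's reactions promoted by ≥ 1
enriched KO.  Each transition into a compound c contributes
C(n, y) p^y (1−p)^(n−y), where n counts the reactions containing c
excluding the reaction the chain arrived by and y the enriched ones among
those n.  The first reaction contributes no term by default (the
transition definition presupposes a previous reaction); an
`include_first` flag adds a term over all reactions at its substrate.
The per-transition binomial is the point mass as defined; an upper-tail
variant (`mode="tail"`) is offered since it is the more conventional
notion of a p-value.  Both choices are labelled in the output.  Motifs
with p-value < 0.05 are marked significant in reports, but all motifs are
emitted regardless.

## Synthetic data generator

The generator is the fixture factory for the whole package and defines
the reference study conditions:

| parameter | default | rationale |
|---|---|---|
| pathways | 148 | size of the metabolic-pathway universe being emulated |
| KO pool | 2,000 | order of distinct KOs seen in marine annotation tables |
| compound pool | 300 | yields a well-connected compound-sharing network |
| background / subset records | 200,000 / 2,000 | a 1% subset, the planted-fixture scale used throughout validation |
| planted KOs | 10 at fold 20 | detectable-effect regime for the recovery suite |
| background abundance | 10^U(0,3) | heavy-tailed KO abundance, mimicking real rank-abundance curves |
| planted baseline | 10^U(2,3) | planted KOs are drawn common in the background — auxiliary metabolic genes are host genes of abundant function, and a fold-20 signal on a vanishingly rare KO is statistically invisible at this depth by design |
| e-values | 10^U(−20,−3) | ~12% of records fail the e < 1e-5 filter |
| identities | U(50,100) | half fail an identity > 75 filter when enabled |
| cluster fraction | 0.1 | exercises cluster expansion at realistic rates |

Superset design: background reads are drawn i.i.d. from the abundance
law; the subset is a weighted sample *without replacement* of background
reads (weight = the planted fold of the read's KO), implemented with
Gumbel top-k keys so it is O(N) and deterministic under the seed.  This
guarantees the superset invariant — every subset (read, KO) record exists
in the background — which the enrichment stage's k ≤ K precondition
requires.  Clusters are formed only among records already passing the
e-value filter and take their members' minimum e-value, so
expansion-then-filtering cannot create a subset count exceeding its
background count.  Paired design: virome and microbiome are independent
draws, the virome from the fold-re-weighted law.

What the generator does **not** emulate: sequence content (the pipeline
starts at annotations), phylogenetic correlation between reads,
compositional coupling between KO abundances, KO-to-pathway structure of
real KEGG maps, or any relationship between a pathway's enrichment and
its network centrality.  Passing the recovery suites therefore
demonstrates the statistical machinery (calibration of the tests, exact
recovery of planted abundance signal), not that real viromes will show
the published biology; in particular the network-level comparisons are
null on default synthetic data, by construction.

## Problem sizes used in validation

The recovery suite runs 50 seeds of the default scenario (200k background
records each) and checks ≥ 95% sensitivity for the planted KOs together
with per-seed false-positive counts inside the 99.9% binomial(m, 1e-4)
envelope.  Exactness suites enumerate all hypergeometric parameter
combinations with N ≤ 12, all binary vectors of length ≤ 10 for the mHG
DP, and 200 random reaction graphs of ≤ 12 reactions against an
independent exhaustive motif oracle.  These sizes are chosen so each
suite proves the property by complete enumeration at small scale while
the whole validation run stays in the minutes range on one core.

## Known limitations

- The mHG DP is exact but O(L·B) rational-arithmetic cells; it is meant
  for pathway-scale vectors (hundreds of entries), not genome-scale
  ranked lists.
- Motif enumeration is exponential in dense reaction graphs; pathway maps
  are small, but adversarial graphs are not protected against.
- In the paired (Fisher) design the two samples are treated as
  independent; shared contamination between size fractions is not
  modelled.
- Degree ties in the mHG ranking are broken lexicographically; rankings
  with many ties should be checked with the sampling validation mode.
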