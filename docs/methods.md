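# Methods

This note documents the statistical models, algorithms and design
choices behind `myonet`, and what the synthetic-data experiments do and
do not demonstrate.

## Differential expression

The built-in test is a per-gene negative-binomial Wald test chosen to
reproduce the *decision structure* of standard RNA-seq tools (log₂ fold
change, raw p, BH FDR, thresholded calls) without binding the pipeline
to any one of them; users who want edgeR or limma estimates can inject
per-timepoint DE tables and skip the built-in test entirely.

* **Low-count filter.** A gene is kept if its raw count reaches
  `min_count` (default 10) in at least `min_samples` samples, where the
  default `min_samples` is the smallest condition × timepoint group size
  (4 in the emulated design). The filter is applied once, before any
  comparison, and an empty result is legal.
* **Normalization.** Median-of-ratios size factors: the per-sample
  median of log count minus log per-gene geometric mean over genes
  positive in all samples, exponentiated. When no gene is positive
  everywhere the factors fall back to total-count ratios.
* **Dispersion.** Method-of-moments per gene, pooled across the two
  groups (var = μ + φμ² ⇒ φ̂ = (s² − μ̄)/μ̄²), clipped to [0, 10],
  then shrunk 50/50 toward a trend computed as the mean φ̂ within
  log-mean deciles (the global mean when fewer than 50 genes). The
  shrinkage stabilises the 4 vs 4 comparisons where genewise moment
  estimates are very noisy; it is deliberately simple and makes no
  claim of parity with empirical-Bayes machinery.
* **Wald test.** log₂FC is computed from the normalized group means
  (disease over control), with a 0.5 pseudo-count substituted only when
  a group mean estimate is exactly 0. The delta-method variance of the
  log mean of n NB(μ, φ) draws is (1/μ + φ)/n, so
  SE(log₂FC) = √[(1/μ_d + φ)/n_d + (1/μ_c + φ)/n_c] / ln 2 and
  z = log₂FC / SE is referred to a standard normal (two-sided).
* **Multiplicity and calls.** BH adjustment is applied per timepoint
  over all genes tested at that timepoint. "Two-fold change" is
  interpreted on the model estimate, |log₂FC| ≥ 1, not on raw CPM
  ratios; calls are induced/repressed at FDR < 0.01 with the sign of
  the fold change, otherwise `ns`.

On all-null simulations at the design's sample sizes the observed
false-call fraction at FDR 0.01 is well below 1% (the call also requires
|log₂FC| ≥ 1, which null genes rarely reach), and an 8-fold planted
effect at moderate depth is called with >95% power (both computed in the
test suite and the acceptance script, not quoted from elsewhere).

## Temporal groups

The seven groups are the onset × persistence × direction product over
the call triples (early, mid, late):

| pattern (D_early, D_mid, D_late) | label |
|---|---|
| induced, induced, induced | EPi |
| ns, induced, induced | MPi |
| ns, repressed, repressed | MPr |
| ns, induced, ns | MTi |
| ns, repressed, ns | MTr |
| ns, ns, induced | LTi |
| ns, ns, repressed | LTr |

Any other pattern with ≥1 significant call (sign reversals, early-only,
early+late without mid, early-onset not persisting) is `unclassified`;
genes never significant are excluded from the grouping output. The rule
table is an explicit, user-replaceable mapping (YAML), so additional
categories (e.g. an early-only class) can be defined without code
changes. This is the minimal rule set consistent with the group names;
other conventions are possible, which is exactly why the table is
configurable.

## Enrichment

`fisher_enrich` computes the one-sided Fisher's exact p as the
hypergeometric upper tail P(X ≥ overlap) after intersecting both the
group and the set with the universe. The default universe for the
pipeline is the set of genes passing the expression filter intersected
with genes annotated to at least one set in the collection. Odds ratios
use the sample OR of the 2×2 table with a Haldane–Anscombe 0.5
correction when any cell is zero; the 95% CI is Woolf's
exp(ln OR ± 1.96·SE) with SE = √(Σ 1/cell). BH adjustment runs within
each pathway category by default (a `global` scope is available),
mirroring analyses that test pathway categories separately.

## Fisher-combined gene scores

s(g) = −log₁₀ P(χ²_{2T} ≥ −2 Σ_t ln q_t(g)) over the T = 3 timepoints.
The combined values default to the BH-adjusted FDRs (matching a score
defined as −log₁₀ of aggregated FDR); a `use="p"` switch combines raw
p-values instead, which is the setting under which Fisher's method has
its exact chi-square null. Inputs are clamped to [1e-300, 1] before
logging and the output tail probability to the same floor, so scores
are finite (≤ 300) even for zero FDRs. Genes missing from a timepoint
contribute q = 1. The score is monotone: lowering any q_t never lowers
s(g) (property-tested).

## Active-module extraction

With prizes w(v) = s(v) − θ, module extraction is a maximum-weight
connected subgraph (MWCS) search — the node-prize form of the
prize-collecting Steiner tree. The heuristic, per connected component:

1. terminals = nodes with w ≥ 0; penalties p(v) = max(−w(v), 0);
2. node-weighted shortest paths between terminals (Dijkstra where a
   path costs the summed penalties of the nodes entered after the
   source; terminals cost 0), giving the terminal metric closure;
3. Kruskal MST of the closure (Kou–Markowsky–Berman approximation),
   expanded back to the underlying paths;
4. the union-of-paths subgraph is reduced to a deterministic Kruskal
   spanning tree (edge cost = summed endpoint penalties) and pruned by
   an **exact** maximum-weight connected subtree dynamic program
   (best(v) = w(v) + Σ_children max(0, best(c))), which subsumes
   iterative negative-leaf pruning and is exact whenever the parent
   graph is a tree.

Ties break lexicographically on gene symbols everywhere (heap order,
edge sort, root choice), so results are bit-reproducible across
platforms. Among components the module with maximal net weight, then
larger size, then lexicographically smallest node set wins. Children
contributing exactly 0 are kept (larger module preferred at equal
weight). Untested network genes score 0 and can therefore enter only as
linkers.

θ is chosen by scanning up to 40 evenly spaced quantiles of the distinct
node scores from high to low and accepting the first θ whose module size
falls inside `size_range` (default 30–60, the scale of the published
EAM module); if no θ lands in range, the module with nearest size is
returned and flagged. Because the scan accepts the *first* (highest) θ
in range, the returned module is the smallest in-range set of
top-scoring genes plus linkers — recovery experiments therefore set
`size_range` to bracket the known planted size (20 ± 25% → 15–25).

On 50 random 10-node graphs with N(0, 4) weights the heuristic matched
the exhaustive MWCS optimum in every case, and was optimal on all 50
random trees (computed by the test suite's brute-force oracle over all
connected subgraphs).

## Attackness and combinatorial attack

For node set S in a network of N nodes, the default (count-removed)
convention is attackness(S) = (N − G_after)/N with G_after the largest
component size after deleting S. It counts the removed nodes as
disconnected, reaches toward 1, and is monotone under set inclusion
(removing more nodes can only shrink the largest component), which
makes it a sound maximization objective. The alternative
(remaining-only) convention (N − |S| − G_after)/N counts only surviving
nodes; every `AttackRecord` stores N, |S|, G_before and G_after so
either value can be recomputed from the record. Published values whose
denominator convention is ambiguous can be checked under both.

`combinatorial_attack` enumerates all C(|candidates|, k) combinations
exhaustively (k ≤ 5 by default; a 10⁷-combination ceiling guards
against accidental blow-ups — C(50, 5) ≈ 2.1 M is comfortably inside).
Component sizes are computed on a bitmask adjacency representation
(big-integer BFS), which keeps a full k = 4 scan of a 50-node module
under a few seconds. Ranking is by attackness with ties broken
lexicographically on the sorted removed tuple; because |S| is constant
within a scan, ranking by smallest G_after is equivalent under both
conventions. Exactness against brute-force enumeration for k ≤ 3 and
monotonicity over 10,000 random (graph, S, v) triples are verified by
the acceptance tests.

## Drug repurposing

Filters, in order: drop withdrawn rows; drop rows without a defined
mechanism of action; drop promiscuous drugs — more than 5 distinct
target genes by default ("non-promiscuous" has no standard cutoff; the
value is a conservative, configurable choice and promiscuity is counted
on the mechanism-supported, non-withdrawn rows); keep only maximum-phase
rows per (gene, indication). The filter is idempotent. Homology
defaults to uppercase-symbol identity (mouse *Btk* → human *BTK*),
adequate for the immune gene families involved; an explicit two-column
map file overrides it, and one mouse symbol mapping to two human
symbols is rejected. "Approved" targets have max_phase 4; "phased"
targets have max_phase ∈ {2, 3} and no approved drug.
`constrained_attack` is `combinatorial_attack` with candidates
restricted to druggable nodes, optionally conditioned on a base set
(e.g. the targets of established immunosuppressants).

## Synthetic data: what it emulates and what it does not

`simulate_counts` draws NB(μ, φ) counts (var = μ + φμ²) at 2 conditions
× 3 timepoints × 4 replicates, the emulated study design. Baseline
means are log-uniform on [20, 2000]; per-sample library factors are
log-uniform on [0.7, 1.3] (exercising normalization); planted genes
multiply the disease mean by 2^±2 at exactly the timepoints their group
prescribes, so truth labels coincide with the grouping rules by
construction. Defaults: dispersion 0.1 (a typical bulk-tissue scale),
|log₂FC| = 2 for planted effects. A single seed feeds per-stage
substreams, so enlarging the gene panel appends draws without
reshuffling earlier ones and identical seeds are bit-identical.

`simulate_network_and_pathways` builds each pathway as a random
spanning tree plus as many extra edges over its members, with later
pathways reusing a fraction of earlier members, and plants a connected
module by randomized breadth-first growth; at the default 10 pathways ×
30 genes with 20% overlap the merged network has ~250 nodes and ~590
edges. `simulate_bundle` renames the planted module with genes planted
in the persistent temporal groups (EPi, then MPi) so the module is
genuinely high-scoring after differential testing, and names all other
network nodes after null genes.

What passing these tests shows: the inference machinery recovers
planted structure when the generating model matches the analysis
assumptions, the percolation metrics agree exactly with enumeration,
and the whole pipeline is deterministic. What it does not show: realism
of the generator. It omits gene–gene count correlation, outlier
samples, composition effects, varying sequencing depth beyond ±30%,
dispersion–mean relationships estimated from real tissue, partial or
graded effect sizes, and annotation noise in pathway membership — so
recovery rates here are upper bounds on what real data would give.

## Problem sizes and numerical choices

Simulation-based checks use 2,000 genes with 100 planted per group over
20 seeds for the count pipeline, and 20 seeds of the ~250-node network
for module recovery; oracle checks use ≤12-node graphs where exhaustive
enumeration over all subsets is exact. FDR/probability floors are
1e-300; Dijkstra uses a 1e-15 strict-improvement margin; BH output is
clipped to [0, 1]. Degenerate inputs are defined: empty gene sets after
filtering propagate as empty tables, a network with no positive-score
node yields an empty module result, and the empty removal set has
attackness (N − G_before)/N (0 on connected networks).

## Known limitations

* The MWCS heuristic is an approximation; it is exact on trees and
  matched brute force on all random small-graph trials here, but
  carries no worst-case guarantee on dense graphs.
* The Wald test is anticonservative for very low counts (few reads in
  both groups); the low-count filter is assumed to have run first.
* The θ scan returns the smallest in-range module of top-scoring genes;
  if the interesting structure is larger than `size_range`'s lower
  bound by construction, widen the range.
* Combinatorial attack is exhaustive only; k > 5 or candidate sets
  yielding more than 10⁷ combinations are rejected rather than solved
  approximately.
* The default homology map is symbol identity up to case; true
  orthology inference is out of scope.
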