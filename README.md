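# myonet

Network analysis of time-course disease transcriptomes, built around the
analysis design used for experimental autoimmune myocarditis (EAM):
bulk RNA-seq of disease vs control hearts at an early, mid and late
timepoint, integrated with pathway interaction networks to nominate
therapeutic targets and drug-repurposing candidates.

The package is aimed at computational biologists who have a gene-level
count matrix from a two-condition, multi-timepoint design and want a
reproducible route from counts to (a) temporal classes of differential
expression, (b) an "active module" subnetwork of the interaction
network, and (c) a ranking of network nodes — or druggable subsets of
them — whose removal most disconnects that module.

## What it computes

1. **Differential expression per timepoint.** After removing genes that
   do not reach 10 raw reads in at least as many samples as the smallest
   experimental group, a self-contained negative-binomial Wald test
   (median-of-ratios normalization, moment dispersion shrunk toward a
   mean-expression trend) produces per-gene log₂ fold change, p, and
   Benjamini–Hochberg FDR per timepoint. Genes are called induced or
   repressed at FDR < 0.01 and |log₂FC| ≥ 1. Externally produced DE
   tables (e.g. from edgeR/limma) are accepted in place of the built-in
   test.
2. **Temporal groups.** Each gene's call triple across the three
   timepoints maps to one of seven onset × persistence × direction
   groups — EPi, MPi, MPr, MTi, MTr, LTi, LTr — or `unclassified`.
3. **Pathway enrichment.** One-sided Fisher's exact (hypergeometric
   upper-tail) tests of every group against every pathway gene set, with
   BH adjustment per pathway category, plus odds ratios with Woolf 95%
   intervals.
4. **Gene scores over time.** Fisher's combined probability method
   aggregates the per-timepoint FDRs:
   X²(g) = −2·Σ_t ln q_t(g) ~ χ²(2T), and s(g) = −log₁₀ of the
   upper-tail probability.
5. **Active module.** The parent network (merged pathway edge lists) is
   searched for a maximum-weight connected subgraph with node prizes
   s(g) − θ — the node-prize form of the prize-collecting Steiner tree —
   via a Kou–Markowsky–Berman Steiner approximation followed by exact
   tree pruning, scanning θ over score quantiles until the module size
   falls in the requested range.
6. **Attackness and combinatorial attack.** For a removed node set S,
   attackness(S) = (N − G_after)/N, the fraction of the module's N nodes
   outside the largest connected component after deleting S (an
   alternative convention that excludes the removed nodes from the
   numerator is also provided). `combinatorial_attack` exhaustively
   ranks all size-k combinations, optionally restricted to druggable
   candidates and conditioned on a fixed base set such as the targets of
   established therapy.
7. **Drug repurposing.** A ChEMBL-style drug-target table is filtered to
   non-withdrawn, mechanism-supported, non-promiscuous records at the
   maximum clinical phase per (gene, indication), mapped onto module
   genes through a mouse→human homology map, tested for enrichment, and
   fed into the constrained attack search.

A synthetic-data generator (`myonet.synthdata`) produces all inputs with
planted ground truth — NB counts with genes planted in each temporal
group, overlapping pathway networks with a planted connected module, and
drug tables — so the whole pipeline is testable end to end.

## Worked example

```python
import myonet

# 1. simulate a study: 2 conditions x 3 timepoints x 4 replicates,
#    100 genes planted in each of the seven temporal groups
config = myonet.SimConfig(
    n_genes=2000,
    group_sizes={g: 100 for g in myonet.GROUP_LABELS},
    effect_log2fc=2.0,
    seed=1,
)
counts, truth, network, pathways, drugs = myonet.simulate_bundle(config)

# 2. differential expression per timepoint
filtered = myonet.filter_low_counts(counts)
de = myonet.run_differential(filtered)
for tp, table in de.items():
    print(f"day {tp}: {(table['call'] != 'ns').sum()} of {len(table)} genes called")

# 3. temporal groups and Fisher-combined scores
groups = myonet.assign_groups(myonet.call_patterns(de))
print(groups.value_counts().sort_index().to_dict())
scores = myonet.combine_scores(de)

# 4. active module from the merged pathway network
module = myonet.find_subnetwork(network, scores, size_range=(15, 25))
planted = set(truth.module_genes)
jaccard = len(set(module.nodes) & planted) / len(set(module.nodes) | planted)
print(f"module: {len(module)} nodes, Jaccard vs planted truth = {jaccard:.2f}")

# 5. attack the module
profile = myonet.attackness_profile(module.graph)
print(f"most critical node: {profile[0].removed[0]} "
      f"(attackness {profile[0].attackness:.2f})")
top = myonet.combinatorial_attack(module.graph, k=4, top_m=1)[0]
print(f"best 4-node attack: {top.removed} -> {top.attackness:.2f}")

# 6. restrict the attack to druggable nodes
mapped = myonet.map_targets(module.nodes, myonet.filter_drug_table(drugs))
targets = myonet.partition_targets(mapped)
druggable = sorted(targets["approved"] | targets["phased"])
best = myonet.constrained_attack(module.graph, druggable, k=2)[0]
print(f"best druggable pair: {best.removed} -> {best.attackness:.2f}")
```

Output:

```
day 10: 99 of 2000 genes called
day 15: 501 of 2000 genes called
day 21: 501 of 2000 genes called
{'EPi': 93, 'LTi': 102, 'LTr': 102, 'MPi': 104, 'MPr': 98, 'MTi': 98, 'MTr': 105, 'unclassified': 7}
module: 15 nodes, Jaccard vs planted truth = 0.75
most critical node: g00024 (attackness 0.53)
best 4-node attack: ('g00017', 'g00024', 'g00035', 'g00196') -> 0.87
best druggable pair: ('g00024', 'g00035') -> 0.67
```

Reading the numbers: only the 100 EPi genes are induced at day 10, so
day 10 calls ≈ 100; at days 15 and 21 five groups of 100 are
differential. Group recovery is within sampling noise of the planted
sizes. The extracted 15-node module is a subset of the 20-gene planted
module (Jaccard 0.75 — the threshold scan accepts the smallest in-range
module of top-scoring genes). Removing the best four nodes strands 87%
of module nodes outside the giant component; the best pair restricted to
drug-targetable nodes strands 67%.

## Command line

Each stage is also a CLI subcommand over the TSV/GMT/GraphML formats:

```bash
myonet simulate --outdir synth --seed 1     # writes a full input bundle + config.yaml
myonet run-all --config synth/config.yaml   # diffexpr -> ... -> repurpose + manifest.json
myonet de --counts counts.tsv --samples samples.tsv --outdir de/
myonet attack --edges subnetwork.graphml --k 4 --out attack.tsv
```

`run-all` writes every intermediate table plus a `manifest.json`
recording the config, seed, input checksums and per-stage summaries;
reruns on identical inputs are bit-identical.

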