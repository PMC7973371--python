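"""Synthetic inputs emulating a two-condition, three-timepoint RNA-seq
study of autoimmune myocarditis, with planted ground truth.

The generator produces everything the analysis pipeline consumes:

* a negative-binomial count matrix (disease vs control × 3 timepoints ×
  replicates) with genes planted in each of the seven temporal groups,
* a parent interaction network assembled from overlapping pathway edge
  lists with a planted connected high-score module,
* a ChEMBL-style drug-target table with approved/phase-II/phase-III and
  withdrawn records, and
* small fixture graphs whose attackness values are known analytically.

Counts follow NB(mean μ, dispersion φ) with var = μ + φ·μ², the model
the downstream differential test assumes.  Per-sample library sizes are
multiplicative factors drawn log-uniformly.  Randomness is derived from
a single seed via per-stage substreams, so enlarging the gene panel
appends new draws without reshuffling earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import CountsTable
from .enrichment import GeneSet, GeneSetCollection
from .grouping import GROUP_LABELS

#: which timepoint indices (early, mid, late) a planted group perturbs,
#: and in which direction
GROUP_EFFECTS: dict[str, dict[int, int]] = {
    "EPi": {0: +1, 1: +1, 2: +1},
    "MPi": {1: +1, 2: +1},
    "MPr": {1: -1, 2: -1},
    "MTi": {1: +1},
    "MTr": {1: -1},
    "LTi": {2: +1},
    "LTr": {2: -1},
}


class ConfigurationError(ValueError):
    """Raised when simulation parameters are internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of the count simulation.

    Defaults mirror the emulated study design: 4 replicates per
    condition at days 10, 15 and 21, a planted |log2 fold change| of 2,
    NB dispersion 0.1, baseline means log-uniform on [20, 2000] and
    ±30% library-size jitter.
    """

    n_genes: int = 2000
    n_replicates: int = 4
    timepoints: tuple = (10, 15, 21)
    group_sizes: dict[str, int] = field(default_factory=dict)
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    baseline_mean_log_range: tuple[float, float] = (math.log(20.0), math.log(2000.0))
    libsize_factor_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.group_sizes) - set(GROUP_LABELS)
        if unknown:
            raise ConfigurationError(f"unknown group labels: {sorted(unknown)}")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ConfigurationError("group sizes must be nonnegative")
        if sum(self.group_sizes.values()) > self.n_genes:
            raise ConfigurationError(
                "sum of group_sizes exceeds n_genes "
                f"({sum(self.group_sizes.values())} > {self.n_genes})"
            )
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.effect_log2fc < 0:
            raise ConfigurationError("effect_log2fc must be ≥ 0")
        if self.n_replicates < 2:
            raise ConfigurationError("need ≥2 replicates per condition × timepoint")
        if len(self.timepoints) != 3:
            raise ConfigurationError("exactly three timepoints are supported")


@dataclass
class TruthLabels:
    """Planted ground truth: gene -> temporal group ('null' if none) and,
    for network simulations, the planted module gene list."""

    labels: dict[str, str] = field(default_factory=dict)
    module_genes: list[str] = field(default_factory=list)

    def genes_in(self, group: str) -> list[str]:
        return sorted(g for g, lab in self.labels.items() if lab == group)


def _substream(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def simulate_counts(config: SimConfig) -> tuple[CountsTable, TruthLabels]:
    """Simulate the gene × sample count matrix with planted effects.

    A gene planted in group g has its disease-condition mean multiplied
    by 2^(±effect_log2fc) at exactly the timepoints the group's
    membership rule marks significant, with the group's sign; null genes
    share means across conditions.  Identical seeds give bit-identical
    output.
    """
    rng_baseline = _substream(config.seed, 1)
    rng_libsize = _substream(config.seed, 2)
    rng_counts = _substream(config.seed, 3)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    labels: dict[str, str] = {g: "null" for g in genes}
    cursor = 0
    for group in GROUP_LABELS:
        for _ in range(config.group_sizes.get(group, 0)):
            labels[genes[cursor]] = group
            cursor += 1

    lo, hi = config.baseline_mean_log_range
    baseline = np.exp(rng_baseline.uniform(lo, hi, size=config.n_genes))

    sample_ids = []
    meta_rows = []
    for tp in config.timepoints:
        for cond in ("disease", "control"):
            for rep in range(1, config.n_replicates + 1):
                sid = f"d{tp}_{cond}_r{rep}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "condition": cond,
                     "timepoint": tp, "replicate": rep}
                )
    samples = pd.DataFrame(meta_rows).set_index("sample_id")

    f_lo, f_hi = config.libsize_factor_range
    lib = np.exp(rng_libsize.uniform(math.log(f_lo), math.log(f_hi),
                                     size=len(sample_ids)))

    # per-gene, per-sample means
    means = np.tile(baseline[:, None], (1, len(sample_ids)))
    fold = 2.0 ** config.effect_log2fc
    for j, sid in enumerate(sample_ids):
        cond = samples.loc[sid, "condition"]
        tp_index = list(config.timepoints).index(samples.loc[sid, "timepoint"])
        if cond != "disease":
            continue
        for gi, g in enumerate(genes):
            group = labels[g]
            if group == "null":
                continue
            sign = GROUP_EFFECTS[group].get(tp_index)
            if sign is None:
                continue
            means[gi, j] *= fold if sign > 0 else 1.0 / fold
    means *= lib[None, :]

    phi = config.nb_dispersion
    r = 1.0 / phi
    p = r / (r + means)
    matrix = rng_counts.negative_binomial(r, p)
    counts = pd.DataFrame(matrix, index=pd.Index(genes, name="gene"),
                          columns=sample_ids)
    return CountsTable(counts, samples), TruthLabels(labels=labels)


def simulate_network_and_pathways(
    n_pathways: int,
    genes_per_pathway: int,
    overlap_fraction: float,
    planted_module_size: int,
    seed: int = 0,
) -> tuple[nx.Graph, GeneSetCollection, TruthLabels]:
    """Simulate overlapping pathway edge lists, their merged parent
    network, and a planted connected module.

    Each pathway is a connected random graph over its member genes (a
    random spanning tree plus as many extra random edges).  Pathway i>1
    reuses ``overlap_fraction`` of its members from earlier pathways, so
    the merged network is connected with high probability for positive
    overlap.  The planted module is a breadth-first connected subgraph
    of the merged network, recorded in the returned truth labels.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ConfigurationError("overlap_fraction must be in [0, 1]")
    if n_pathways < 1 or genes_per_pathway < 2:
        raise ConfigurationError("need ≥1 pathway of ≥2 genes")
    rng = _substream(seed, 11)
    categories = ("Environmental Information Processing", "Organismal Systems")

    pool: list[str] = []
    next_gene = 0
    edge_lists: dict[str, list[tuple[str, str]]] = {}
    gene_sets = []
    for i in range(n_pathways):
        n_overlap = int(round(overlap_fraction * genes_per_pathway)) if i else 0
        n_overlap = min(n_overlap, len(pool))
        members = ([str(g) for g in rng.choice(pool, size=n_overlap, replace=False)]
                   if n_overlap else [])
        n_fresh = genes_per_pathway - n_overlap
        fresh = [f"NG{j:05d}" for j in range(next_gene, next_gene + n_fresh)]
        next_gene += n_fresh
        members = members + fresh
        pool.extend(fresh)

        order = list(rng.permutation(members))
        edges = set()
        for j in range(1, len(order)):
            k = int(rng.integers(0, j))
            a, b = sorted((order[j], order[k]))
            edges.add((a, b))
        extra_target = genes_per_pathway
        attempts = 0
        while len(edges) < len(order) - 1 + extra_target and attempts < 20 * extra_target:
            u, v = (str(x) for x in rng.choice(members, size=2, replace=False))
            attempts += 1
            if u == v:
                continue
            edges.add(tuple(sorted((u, v))))
        pid = f"path{i + 1:02d}"
        edge_lists[pid] = sorted(edges)
        gene_sets.append(
            GeneSet(pid, f"Simulated pathway {i + 1}",
                    categories[i % 2], frozenset(members))
        )

    from .netbuild import merge_pathway_networks

    network = merge_pathway_networks(edge_lists)
    collection = GeneSetCollection(gene_sets)

    if planted_module_size > network.number_of_nodes():
        raise ConfigurationError(
            "planted_module_size exceeds the simulated gene count"
        )
    components = sorted(nx.connected_components(network), key=len, reverse=True)
    giant = components[0]
    if planted_module_size > len(giant):
        raise ConfigurationError(
            f"no connected component can host a module of {planted_module_size} genes"
        )
    module: list[str] = []
    if planted_module_size > 0:
        start = str(rng.choice(sorted(giant)))
        visited = {start}
        frontier = [start]
        module = [start]
        while len(module) < planted_module_size:
            nxt = sorted(
                {n for v in frontier for n in network.neighbors(v)} - visited
            )
            if not nxt:
                break
            take = min(len(nxt), planted_module_size - len(module))
            picked = [str(x) for x in rng.choice(nxt, size=take, replace=False)]
            module.extend(picked)
            visited.update(picked)
            frontier = picked
        module = sorted(module)

    truth = TruthLabels(
        labels={g: "null" for g in network.nodes()},
        module_genes=module,
    )
    return network, collection, truth


def simulate_module_scores(
    network: nx.Graph,
    module_genes: list[str],
    module_min_score: float = 3.0,
    background_max_score: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """Gene scores with the planted module scored high against a low
    background: module genes draw module_min_score + Exp(1), background
    genes draw Uniform(0, background_max_score)."""
    rng = _substream(seed, 13)
    nodes = sorted(network.nodes())
    module = set(module_genes)
    scores = {}
    for v in nodes:
        if v in module:
            scores[v] = module_min_score + float(rng.exponential(1.0))
        else:
            scores[v] = float(rng.uniform(0.0, background_max_score))
    return pd.Series(scores, name="score")


def simulate_drug_table(
    genes: list[str],
    fraction_approved: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """ChEMBL-style drug-target table over ``genes``.

    Each gene receives one drug row; non-withdrawn rows are approved
    (max_phase 4) with probability ``fraction_approved`` and otherwise
    uniformly phase 1–3.  One withdrawn row and one duplicate
    (gene, indication) pair at phases {2, 4} are always planted so the
    filtering rules are exercised.
    """
    if not genes:
        raise ValueError("gene list must be nonempty")
    if not 0 <= fraction_approved <= 1:
        raise ValueError("fraction_approved must be in [0, 1]")
    rng = _substream(seed, 17)
    indications = ("autoimmune disease", "lymphoma", "arthritis", "asthma")
    rows = []
    for i, gene in enumerate(sorted(genes)):
        approved = rng.uniform() < fraction_approved
        phase = 4 if approved else int(rng.integers(1, 4))
        rows.append(
            {
                "drug_id": f"DRUG{i:04d}",
                "drug_name": f"compound-{i:04d}",
                "gene": gene,
                "max_phase": phase,
                "indication": indications[int(rng.integers(0, len(indications)))],
                "has_moa": True,
                "withdrawn": False,
            }
        )
    # planted withdrawn record
    g0 = sorted(genes)[0]
    rows.append(
        {
            "drug_id": "DRUGWD01",
            "drug_name": "withdrawn-compound",
            "gene": g0,
            "max_phase": 4,
            "indication": indications[0],
            "has_moa": True,
            "withdrawn": True,
        }
    )
    # planted duplicate (gene, indication) at phases 2 and 4
    rows.append(
        {
            "drug_id": "DRUGDUP2",
            "drug_name": "duplicate-low-phase",
            "gene": g0,
            "max_phase": 2,
            "indication": "duplicated indication",
            "has_moa": True,
            "withdrawn": False,
        }
    )
    rows.append(
        {
            "drug_id": "DRUGDUP4",
            "drug_name": "duplicate-high-phase",
            "gene": g0,
            "max_phase": 4,
            "indication": "duplicated indication",
            "has_moa": True,
            "withdrawn": False,
        }
    )
    return pd.DataFrame(rows)


def simulate_bundle(
    config: SimConfig,
    n_pathways: int = 10,
    genes_per_pathway: int = 30,
    overlap_fraction: float = 0.2,
    planted_module_size: int = 20,
    fraction_approved: float = 0.5,
) -> tuple[CountsTable, TruthLabels, nx.Graph, GeneSetCollection, pd.DataFrame]:
    """Generate a coherent input bundle: counts, parent network, pathway
    sets and a drug-target table over one shared gene panel.

    The planted network module is relabelled with genes planted in the
    persistent temporal groups (EPi, then MPi), so after differential
    testing and Fisher-combined scoring the module carries high scores;
    all remaining network nodes take null-gene names.  The drug table
    targets the human (uppercased) symbols of the network genes.
    """
    counts, truth = simulate_counts(config)
    network, collection, net_truth = simulate_network_and_pathways(
        n_pathways, genes_per_pathway, overlap_fraction,
        planted_module_size, seed=config.seed,
    )
    rng = _substream(config.seed, 19)
    module_nodes = net_truth.module_genes
    persistent = truth.genes_in("EPi") + truth.genes_in("MPi")
    if len(module_nodes) > len(persistent):
        raise ConfigurationError(
            "planted module larger than the EPi+MPi gene pool; increase "
            "group_sizes for EPi/MPi"
        )
    null_genes = truth.genes_in("null")
    others = sorted(set(network.nodes()) - set(module_nodes))
    if len(others) > len(null_genes):
        raise ConfigurationError(
            "network background larger than the null gene pool; increase n_genes"
        )
    module_names = [str(x) for x in rng.choice(persistent, size=len(module_nodes),
                                               replace=False)]
    other_names = [str(x) for x in rng.choice(null_genes, size=len(others),
                                              replace=False)]
    mapping = dict(zip(module_nodes, module_names))
    mapping.update(zip(others, other_names))
    network = nx.relabel_nodes(network, mapping)
    collection = GeneSetCollection(
        [
            GeneSet(s.set_id, s.name, s.category,
                    frozenset(mapping[g] for g in s.genes))
            for s in collection
        ]
    )
    drug_table = simulate_drug_table(
        [g.upper() for g in sorted(network.nodes())],
        fraction_approved=fraction_approved, seed=config.seed,
    )
    truth.module_genes = sorted(module_names)
    return counts, truth, network, collection, drug_table


def make_fixture_graphs() -> dict[str, nx.Graph]:
    """Small named graphs with analytically known attackness values.

    * ``star5``: hub plus four leaves (removing the hub strands 4/5 of
      the nodes).
    * ``path3``: three nodes in a line (the middle node is a cut vertex).
    * ``barbell9``: two 4-cliques joined through one bridging cut vertex
      (9 nodes, 14 edges by construction: 2·C(4,2) clique edges plus the
      2 bridge edges).
    """
    star5 = nx.relabel_nodes(nx.star_graph(4), lambda i: f"s{i}")
    path3 = nx.relabel_nodes(nx.path_graph(3), lambda i: f"p{i}")
    barbell9 = nx.relabel_nodes(nx.barbell_graph(4, 1), lambda i: f"b{i}")
    return {"star5": star5, "path3": path3, "barbell9": barbell9}
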