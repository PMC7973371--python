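"""Parent-network assembly, temporal gene scoring, and active-module extraction.

The active-module step treats subnetwork identification as a
maximum-weight connected subgraph (MWCS) problem, the node-prize form of
the prize-collecting Steiner tree: each gene carries a prize
``s(g) - θ`` where ``s(g)`` is the Fisher-combined significance score
over timepoints and θ is a score threshold.  High-scoring genes are
positive-prize "terminals"; genes below θ may enter the module only as
linkers on cheap paths between terminals.  The heuristic is the
Kou–Markowsky–Berman Steiner approximation on the terminal metric
closure, followed by an exact max-weight connected subtree pruning of
the resulting tree.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: floor applied to FDR values before taking logarithms
FDR_FLOOR = 1e-300


def merge_pathway_networks(
    edge_lists: Mapping[str, Iterable[tuple[str, str]]],
) -> nx.Graph:
    """Merge per-pathway edge lists into one simple undirected network.

    Duplicate edges are collapsed with pathway provenance accumulated in
    the ``pathways`` edge attribute (a sorted tuple); self-loops are
    dropped with a warning.  Edge (a, b) is identified with (b, a).
    """
    graph = nx.Graph()
    for pathway_id, edges in edge_lists.items():
        for row_no, edge in enumerate(edges, start=1):
            try:
                a, b = edge[0], edge[1]
            except (TypeError, IndexError) as exc:
                raise ValueError(
                    f"malformed edge row {row_no} in pathway {pathway_id!r}: {edge!r}"
                ) from exc
            if not a or not b:
                raise ValueError(
                    f"empty gene symbol at row {row_no} in pathway {pathway_id!r}"
                )
            if a == b:
                logger.warning(
                    "dropping self-loop (%s, %s) at row %d of pathway %s",
                    a, b, row_no, pathway_id,
                )
                continue
            if graph.has_edge(a, b):
                prov = set(graph.edges[a, b]["pathways"])
                prov.add(pathway_id)
                graph.edges[a, b]["pathways"] = tuple(sorted(prov))
            else:
                graph.add_edge(a, b, pathways=(pathway_id,))
    return graph


def combine_scores(
    de_tables: Mapping[object, pd.DataFrame],
    use: str = "fdr",
) -> pd.Series:
    """Per-gene significance score combined over timepoints.

    Applies Fisher's combined probability method to the per-timepoint
    significance values: X²(g) = -2·Σ_t ln q_t(g) is referred to a
    chi-square distribution with 2·T degrees of freedom (T timepoints),
    and the score is s(g) = -log10 of the upper-tail probability.  A
    gene missing from a table contributes q = 1; values are clamped to
    [1e-300, 1] before taking logarithms so scores stay finite.

    Parameters
    ----------
    de_tables
        Mapping timepoint -> differential-expression table with columns
        ``gene`` and ``fdr`` (and ``p``).
    use
        Which column to combine: ``"fdr"`` (default, matching a score
        defined on FDR-adjusted values) or ``"p"``.
    """
    if use not in ("fdr", "p"):
        raise ValueError(f"use must be 'fdr' or 'p', got {use!r}")
    if not de_tables:
        raise ValueError("no differential-expression tables supplied")
    genes: list[str] = sorted(
        set().union(*(set(t["gene"]) for t in de_tables.values()))
    )
    n_t = len(de_tables)
    values = np.ones((len(genes), n_t))
    gene_ix = {g: i for i, g in enumerate(genes)}
    for j, (_, table) in enumerate(sorted(de_tables.items(), key=lambda kv: str(kv[0]))):
        col = table[use].to_numpy(dtype=float)
        if np.any((col < 0) | (col > 1) | ~np.isfinite(col)):
            raise ValueError(f"{use} values outside [0, 1]")
        for g, v in zip(table["gene"], col):
            values[gene_ix[g], j] = v
    clamped = np.clip(values, FDR_FLOOR, 1.0)
    x2 = -2.0 * np.log(clamped).sum(axis=1)
    combined_p = stats.chi2.sf(x2, df=2 * n_t)
    score = -np.log10(np.clip(combined_p, FDR_FLOOR, 1.0))
    return pd.Series(score, index=pd.Index(genes, name="gene"), name="score")


@dataclass
class SubnetworkResult:
    """Connected module extracted from a parent network.

    Attributes
    ----------
    graph
        Induced subgraph of the parent network on the module nodes; node
        attributes carry per-gene scores (and, when annotated, the
        per-timepoint fold changes and FDRs).
    threshold
        The score threshold θ at which the module was extracted.
    net_weight
        Total prize Σ (s(g) - θ) over module nodes.
    size_in_range
        Whether the module size landed inside the requested range.
    """

    graph: nx.Graph
    threshold: float
    net_weight: float
    size_in_range: bool = True
    scores: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes())

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def _node_weighted_dijkstra(
    graph: nx.Graph, source: str, penalty: Mapping[str, float]
) -> tuple[dict[str, float], dict[str, str]]:
    """Shortest paths where the cost of a path is the summed penalty of
    the nodes entered after the source.  Terminal nodes carry zero
    penalty, so terminal-to-terminal costs count interior linkers only.

    Determinism: the heap orders ties by node symbol and neighbors are
    relaxed in sorted order, so predecessors are platform-independent.
    """
    dist = {source: 0.0}
    pred: dict[str, str] = {}
    heap: list[tuple[float, str]] = [(0.0, source)]
    done: set[str] = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in sorted(graph.neighbors(u)):
            if v in done:
                continue
            nd = d + penalty[v]
            if v not in dist or nd < dist[v] - 1e-15:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
    return dist, pred


def _expand_path(pred: Mapping[str, str], target: str) -> list[str]:
    path = [target]
    while path[-1] in pred:
        path.append(pred[path[-1]])
    return path


def _max_weight_subtree(
    tree: nx.Graph, weight: Mapping[str, float]
) -> tuple[set[str], float]:
    """Exact maximum-weight connected subtree of a tree by dynamic
    programming: best(v) = w(v) + Σ_children max(0, best(c)).

    Children with best(c) == 0 are included (larger module preferred at
    equal weight); root ties break on (weight, size, node symbol).
    """
    root = min(tree.nodes())
    order = list(nx.dfs_preorder_nodes(tree, root))
    parent = {root: None}
    for u in order:
        for v in tree.neighbors(u):
            if v != root and v not in parent:
                parent[v] = u
    best: dict[str, float] = {}
    size: dict[str, int] = {}
    for v in reversed(order):
        b = weight[v]
        s = 1
        for c in tree.neighbors(v):
            if parent.get(c) == v:
                if best[c] >= 0.0:
                    b += best[c]
                    s += size[c]
        best[v] = b
        size[v] = s
    top = sorted(tree.nodes(), key=lambda v: (-best[v], -size[v], v))[0]
    # reconstruct: include top's subtree members whose best is nonnegative
    chosen = {top}
    stack = [top]
    while stack:
        u = stack.pop()
        for c in sorted(tree.neighbors(u)):
            if parent.get(c) == u and best[c] >= 0.0:
                chosen.add(c)
                stack.append(c)
    return chosen, best[top]


def _mwcs_component(
    graph: nx.Graph, weight: Mapping[str, float]
) -> tuple[set[str], float] | None:
    """MWCS heuristic on one connected graph: KMB Steiner approximation
    over the nonnegative-weight terminals, then exact tree pruning."""
    terminals = sorted(v for v in graph if weight[v] >= 0.0)
    if not terminals:
        return None
    if len(terminals) == 1:
        return {terminals[0]}, weight[terminals[0]]
    penalty = {v: max(-weight[v], 0.0) for v in graph}
    # metric closure over terminals with interior-penalty path costs
    closure_edges: list[tuple[float, str, str]] = []
    paths: dict[tuple[str, str], list[str]] = {}
    for t in terminals:
        dist, pred = _node_weighted_dijkstra(graph, t, penalty)
        for u in terminals:
            if u <= t or u not in dist:
                continue
            closure_edges.append((dist[u], t, u))
            paths[(t, u)] = _expand_path(pred, u)
    if not closure_edges:
        return {terminals[0]}, weight[terminals[0]]
    # Kruskal MST of the closure (sorted for deterministic tie-breaks)
    closure_edges.sort()
    parent = {t: t for t in terminals}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    union_nodes: set[str] = set()
    union_edges: set[tuple[str, str]] = set()
    for cost, a, b in closure_edges:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        parent[ra] = rb
        path = paths[(a, b)]
        union_nodes.update(path)
        for u, v in zip(path, path[1:]):
            union_edges.add((min(u, v), max(u, v)))
    steiner = nx.Graph()
    steiner.add_nodes_from(union_nodes)
    steiner.add_edges_from(union_edges)
    # reduce the path union to a tree (cheapest edges by endpoint penalty),
    # then prune it exactly
    tree = _kruskal_tree(steiner, penalty)
    return _max_weight_subtree(tree, weight)


def _kruskal_tree(graph: nx.Graph, penalty: Mapping[str, float]) -> nx.Graph:
    """Deterministic Kruskal spanning tree of a connected graph with edge
    cost = summed endpoint penalties, ties broken lexicographically."""
    edges = sorted(
        (penalty[u] + penalty[v], min(u, v), max(u, v)) for u, v in graph.edges()
    )
    parent = {v: v for v in graph.nodes()}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = nx.Graph()
    tree.add_nodes_from(graph.nodes())
    for _, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.add_edge(u, v)
    return tree


def mwcs_heuristic(
    network: nx.Graph, weights: Mapping[str, float]
) -> tuple[set[str], float]:
    """Best-effort maximum-weight connected subgraph of ``network``.

    Runs the Steiner/pruning heuristic on every connected component that
    contains a nonnegative-weight node and returns the best module by
    (net weight, size, lexicographically smallest node set).  Returns an
    empty set when no node has nonnegative weight.
    """
    best: tuple[float, int, list[str]] | None = None
    best_nodes: set[str] = set()
    for comp in nx.connected_components(network):
        sub = network.subgraph(comp)
        result = _mwcs_component(sub, weights)
        if result is None:
            continue
        nodes, net = result
        cand = (net, len(nodes), sorted(nodes))
        if best is None or (cand[0], cand[1]) > (best[0], best[1]) or (
            (cand[0], cand[1]) == (best[0], best[1]) and cand[2] < best[2]
        ):
            best = cand
            best_nodes = nodes
    if best is None:
        return set(), 0.0
    return best_nodes, best[0]


def find_subnetwork(
    network: nx.Graph,
    scores: Mapping[str, float] | pd.Series,
    size_range: tuple[int, int] = (30, 60),
    n_thresholds: int = 40,
) -> SubnetworkResult:
    """Extract the highest-scoring connected module from a parent network.

    The score threshold θ is chosen by scanning candidate values from
    high to low over the quantiles of the node scores; the first θ whose
    module size falls within ``size_range`` is accepted.  If no
    threshold achieves the requested range, the module with size nearest
    the range is returned (``size_in_range`` is False).  Genes present
    in the network but absent from ``scores`` receive score 0 and can
    enter the module only as linkers.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot extract a subnetwork from an empty network")
    n_min, n_max = size_range
    if not 1 <= n_min <= n_max:
        raise ValueError(f"invalid size_range {size_range}")
    s = {v: float(scores.get(v, 0.0)) for v in network.nodes()}
    if not any(v > 0.0 for v in s.values()):
        logger.warning("no positive-score nodes; returning an empty module")
        return SubnetworkResult(nx.Graph(), threshold=0.0, net_weight=0.0,
                                size_in_range=False, scores={})
    values = np.array(sorted(set(s.values())))
    if len(values) <= n_thresholds:
        thresholds = values[::-1]
    else:
        qs = np.linspace(1.0, 0.0, n_thresholds)
        thresholds = np.unique(np.quantile(values, qs))[::-1]
    fallback: tuple[int, float, float, set[str]] | None = None  # (dist, -net, θ, nodes)
    for theta in thresholds:
        weights = {v: s[v] - theta for v in s}
        nodes, net = mwcs_heuristic(network, weights)
        size = len(nodes)
        if size == 0:
            continue
        if n_min <= size <= n_max:
            return _build_result(network, nodes, s, float(theta), True)
        dist = n_min - size if size < n_min else size - n_max
        cand = (dist, -net, float(theta), nodes)
        if fallback is None or cand[:2] < fallback[:2]:
            fallback = cand
    if fallback is None:
        logger.warning("no threshold produced a module; returning empty result")
        return SubnetworkResult(nx.Graph(), threshold=0.0, net_weight=0.0,
                                size_in_range=False, scores={})
    _, _, theta, nodes = fallback
    logger.warning(
        "no threshold achieved size range %s; returning nearest size %d",
        size_range, len(nodes),
    )
    return _build_result(network, nodes, s, theta, False)


def _build_result(
    network: nx.Graph,
    nodes: set[str],
    scores: Mapping[str, float],
    theta: float,
    in_range: bool,
) -> SubnetworkResult:
    sub = nx.Graph(network.subgraph(nodes))
    node_scores = {v: scores[v] for v in nodes}
    nx.set_node_attributes(sub, node_scores, "score")
    net_weight = sum(scores[v] - theta for v in nodes)
    return SubnetworkResult(sub, theta, net_weight, in_range, node_scores)


def annotate_subnetwork(
    result: SubnetworkResult, de_tables: Mapping[object, pd.DataFrame]
) -> SubnetworkResult:
    """Attach per-timepoint log2 fold change and FDR as node attributes."""
    for tp, table in de_tables.items():
        lfc = dict(zip(table["gene"], table["log2fc"]))
        fdr = dict(zip(table["gene"], table["fdr"]))
        for v in result.graph.nodes():
            result.graph.nodes[v][f"log2fc_d{tp}"] = float(lfc.get(v, float("nan")))
            result.graph.nodes[v][f"fdr_d{tp}"] = float(fdr.get(v, float("nan")))
    return result
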