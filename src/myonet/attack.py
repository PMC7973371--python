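"""Network percolation under targeted node removal.

The vulnerability of a gene network to removal of a node set S is
quantified by "attackness": the fraction of network nodes disconnected
from the giant (largest connected) component after deleting S.  Two
denominator conventions are supported:

``count-removed`` (default)
    attackness(S) = (N - G_after) / N, where N is the original node
    count and G_after the largest component size after deletion.
    Removed nodes themselves count as disconnected.  This convention is
    monotone under set inclusion, which makes it a sound objective for
    combinatorial maximization.

``remaining-only``
    attackness(S) = (N - |S| - G_after) / N.  Only surviving nodes
    outside the giant component count.

Every :class:`AttackRecord` stores all component sizes, so a value
under either convention can be recomputed from the record.
"""

from __future__ import annotations

import itertools
from bisect import insort
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

CONVENTIONS = ("count-removed", "remaining-only")

#: default ceiling on the combination size k (configurable per call)
MAX_K = 5

#: exhaustive enumeration limit on the number of candidate combinations
EXHAUSTIVE_LIMIT = 10_000_000


@dataclass(frozen=True)
class AttackRecord:
    """Outcome of removing one node set from a network."""

    removed: tuple[str, ...]
    attackness: float
    n_nodes: int
    giant_before: int
    giant_after: int
    convention: str

    def value_under(self, convention: str) -> float:
        """Recompute the attackness under either convention."""
        if convention == "count-removed":
            return (self.n_nodes - self.giant_after) / self.n_nodes
        if convention == "remaining-only":
            return (self.n_nodes - len(self.removed) - self.giant_after) / self.n_nodes
        raise ValueError(f"unknown convention: {convention!r}")


def giant_component_size(network: nx.Graph) -> int:
    """Size of the largest connected component (0 for an empty graph)."""
    if network.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(network))


def _validate_convention(convention: str) -> None:
    if convention not in CONVENTIONS:
        raise ValueError(
            f"unknown convention {convention!r}; expected one of {CONVENTIONS}"
        )


def attackness(
    network: nx.Graph,
    removed: Iterable[str],
    convention: str = "count-removed",
) -> AttackRecord:
    """Attackness of removing the node set ``removed`` from ``network``."""
    _validate_convention(convention)
    if network.number_of_nodes() == 0:
        raise ValueError("attackness is undefined on an empty network")
    removed = tuple(sorted(set(removed)))
    missing = [v for v in removed if v not in network]
    if missing:
        raise ValueError(f"removed nodes absent from network: {missing}")
    n = network.number_of_nodes()
    g_before = giant_component_size(network)
    surviving = network.subgraph(v for v in network if v not in set(removed))
    g_after = giant_component_size(surviving)
    if convention == "count-removed":
        value = (n - g_after) / n
    else:
        value = (n - len(removed) - g_after) / n
    return AttackRecord(removed, value, n, g_before, g_after, convention)


def attackness_profile(
    network: nx.Graph, convention: str = "count-removed"
) -> list[AttackRecord]:
    """Single-node attackness for every node, sorted descending.

    Ties are broken lexicographically by node symbol so output order is
    reproducible across runs and platforms.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("attackness profile requires a nonempty network")
    records = [attackness(network, [v], convention) for v in network]
    records.sort(key=lambda r: (-r.attackness, r.removed))
    return records


class _BitsetGraph:
    """Adjacency bitmask representation for fast component scans.

    Nodes are indexed in lexicographic order; a component search over a
    50-node graph costs a handful of big-int operations, which keeps
    exhaustive enumeration of ~10^6 combinations tractable.
    """

    def __init__(self, network: nx.Graph):
        self.nodes = sorted(network.nodes())
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.n = len(self.nodes)
        adj = [0] * self.n
        for u, v in network.edges():
            i, j = self.index[u], self.index[v]
            adj[i] |= 1 << j
            adj[j] |= 1 << i
        self.adj = adj
        self.full = (1 << self.n) - 1

    def mask(self, nodes: Iterable[str]) -> int:
        m = 0
        for v in nodes:
            m |= 1 << self.index[v]
        return m

    def giant_after(self, removed_mask: int) -> int:
        """Largest component size after deleting the masked nodes."""
        remaining = self.full & ~removed_mask
        adj = self.adj
        best = 0
        while remaining:
            comp = remaining & -remaining
            frontier = comp
            while frontier:
                nbrs = 0
                f = frontier
                while f:
                    b = f & -f
                    nbrs |= adj[b.bit_length() - 1]
                    f ^= b
                frontier = nbrs & remaining & ~comp
                comp |= frontier
            remaining &= ~comp
            size = comp.bit_count()
            if size > best:
                best = size
        return best


def combinatorial_attack(
    network: nx.Graph,
    k: int,
    candidates: Iterable[str] | None = None,
    base_set: Iterable[str] = (),
    top_m: int = 10,
    convention: str = "count-removed",
    max_k: int = MAX_K,
) -> list[AttackRecord]:
    """Rank size-``k`` node combinations by the attackness of their removal.

    Evaluates attackness(base_set ∪ C) over all combinations C of size
    ``k`` drawn from ``candidates`` (default: all nodes outside
    ``base_set``) and returns the ``top_m`` records, ranked by
    attackness with ties broken lexicographically on the sorted removed
    node tuple.  Enumeration is exhaustive; the candidate space must
    stay within ``EXHAUSTIVE_LIMIT`` combinations.
    """
    _validate_convention(convention)
    if not 1 <= k <= max_k:
        raise ValueError(f"combination size k={k} outside allowed range 1–{max_k}")
    base = tuple(sorted(set(base_set)))
    if candidates is None:
        cand = sorted(set(network.nodes()) - set(base))
    else:
        cand = sorted(set(candidates))
    overlap = set(base) & set(cand)
    if overlap:
        raise ValueError(f"base_set and candidates overlap: {sorted(overlap)}")
    missing = [v for v in itertools.chain(base, cand) if v not in network]
    if missing:
        raise ValueError(f"nodes absent from network: {missing}")
    n = network.number_of_nodes()
    if len(base) + k > n:
        raise ValueError("base_set plus k exceeds the number of network nodes")
    import math

    n_comb = math.comb(len(cand), k)
    if n_comb > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"{n_comb} combinations exceed the exhaustive limit; "
            "restrict the candidate set or lower k"
        )

    bg = _BitsetGraph(network)
    base_mask = bg.mask(base)
    g_before = bg.giant_after(0)

    # top_m smallest (g_after, removed-tuple) keys; smaller giant component
    # after removal means higher attackness under either convention because
    # |S| is fixed across the enumeration.
    best: list[tuple[int, tuple[str, ...]]] = []
    for combo in itertools.combinations(cand, k):
        g_after = bg.giant_after(base_mask | bg.mask(combo))
        if len(best) == top_m and g_after > best[-1][0]:
            continue
        key = (g_after, tuple(sorted(base + combo)))
        if len(best) == top_m:
            if key >= best[-1]:
                continue
            best.pop()
        insort(best, key)

    records = []
    for g_after, removed in best:
        if convention == "count-removed":
            value = (n - g_after) / n
        else:
            value = (n - len(removed) - g_after) / n
        records.append(
            AttackRecord(removed, value, n, g_before, g_after, convention)
        )
    return records
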