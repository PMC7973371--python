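import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from myonet import CountsTable, make_fixture_graphs


# ---------------------------------------------------------------------------
# independent oracles (deliberately avoid networkx algorithms so they can
# cross-check the implementation)

def dfs_components(nodes, edges):
    """Connected components by plain stack DFS over an adjacency dict."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def brute_attackness(graph, removed, convention="count-removed"):
    """Attackness by component enumeration, independent of the package."""
    removed = set(removed)
    nodes = [v for v in graph.nodes() if v not in removed]
    edges = [(u, v) for u, v in graph.edges()
             if u not in removed and v not in removed]
    comps = dfs_components(nodes, edges)
    g_after = max((len(c) for c in comps), default=0)
    n = graph.number_of_nodes()
    if convention == "count-removed":
        return (n - g_after) / n
    return (n - len(removed) - g_after) / n


def brute_mwcs(graph, weights):
    """Exhaustive maximum-weight connected subgraph (small graphs only)."""
    best_net, best_nodes = -np.inf, set()
    nodes = sorted(graph.nodes())
    for r in range(1, len(nodes) + 1):
        for comb in itertools.combinations(nodes, r):
            sub_nodes = set(comb)
            comps = dfs_components(
                comb,
                [(u, v) for u, v in graph.edges()
                 if u in sub_nodes and v in sub_nodes],
            )
            if len(comps) != 1:
                continue
            net = sum(weights[v] for v in comb)
            if net > best_net:
                best_net, best_nodes = net, sub_nodes
    return best_net, best_nodes


def random_graph(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, lambda i: f"v{i:02d}")


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def fixture_graphs():
    return make_fixture_graphs()


@pytest.fixture()
def tiny_counts():
    """2 genes × 12 samples (2 conditions × 3 timepoints × 2 replicates)."""
    samples = []
    for tp in (10, 15, 21):
        for cond in ("disease", "control"):
            for rep in (1, 2):
                samples.append((f"d{tp}_{cond}_r{rep}", cond, tp, rep))
    meta = pd.DataFrame(
        samples, columns=["sample_id", "condition", "timepoint", "replicate"]
    ).set_index("sample_id")
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(100, size=(2, len(meta))),
        index=pd.Index(["gA", "gB"], name="gene"),
        columns=meta.index,
    )
    return CountsTable(counts, meta)
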