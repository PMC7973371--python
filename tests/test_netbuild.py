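"""Network merging, Fisher-combined scoring, and module extraction."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myonet import (
    combine_scores,
    find_subnetwork,
    merge_pathway_networks,
    mwcs_heuristic,
)
from conftest import brute_mwcs, random_graph


def de_frame(fdrs, genes=None):
    genes = genes or [f"g{i}" for i in range(len(fdrs))]
    return pd.DataFrame(
        {"gene": genes, "log2fc": 0.0, "p": fdrs, "fdr": fdrs, "call": "ns"}
    )


class TestMerge:
    def test_single_pathway(self):
        g = merge_pathway_networks({"p1": [("A", "B"), ("B", "C")]})
        assert sorted(g.nodes()) == ["A", "B", "C"]
        assert g.number_of_edges() == 2

    def test_shared_edge_collapsed_with_provenance(self):
        g = merge_pathway_networks(
            {"p1": [("A", "B")], "p2": [("B", "A"), ("B", "C")]}
        )
        assert g.number_of_edges() == 2
        assert g.edges["A", "B"]["pathways"] == ("p1", "p2")

    def test_self_loop_dropped(self, caplog):
        with caplog.at_level("WARNING"):
            g = merge_pathway_networks({"p1": [("A", "A"), ("A", "B")]})
        assert g.number_of_edges() == 1
        assert "self-loop" in caplog.text

    def test_malformed_row_reports_line(self):
        with pytest.raises(ValueError, match="row 2"):
            merge_pathway_networks({"p1": [("A", "B"), ("C",)]})

    def test_merge_idempotent(self):
        edges = {"p1": [("A", "B"), ("B", "C")], "p2": [("C", "D")]}
        once = merge_pathway_networks(edges)
        again = merge_pathway_networks(
            {"m": [(u, v) for u, v in once.edges()]}
        )
        assert set(once.edges()) == set(again.edges())
        assert set(once.nodes()) == set(again.nodes())


class TestCombineScores:
    def chi2_sf_df6(self, x):
        # closed-form survival function of chi-square with 6 df
        return math.exp(-x / 2) * (1 + x / 2 + x * x / 8)

    @pytest.mark.parametrize(
        "fdr, expected",
        [
            (1.0, 0.0),
            (0.5, 0.1836360),  # -log10 of closed-form p ≈ 0.6552
            (0.01, 3.9576227),  # combined p ≈ 1.09e-4
        ],
    )
    def test_matches_df6_closed_form(self, fdr, expected):
        tables = {tp: de_frame([fdr], ["g"]) for tp in (10, 15, 21)}
        score = combine_scores(tables)["g"]
        x2 = -2 * 3 * math.log(fdr) if fdr < 1 else 0.0
        closed = -math.log10(self.chi2_sf_df6(x2)) if x2 > 0 else 0.0
        assert score == pytest.approx(expected, abs=1e-6)
        assert score == pytest.approx(closed, abs=1e-12)

    def test_missing_gene_counts_as_one(self):
        tables = {
            10: de_frame([0.01], ["g1"]),
            15: de_frame([0.01, 0.01], ["g1", "g2"]),
            21: de_frame([0.01, 0.01], ["g1", "g2"]),
        }
        scores = combine_scores(tables)
        assert scores["g2"] < scores["g1"]

    def test_invalid_fdr_rejected(self):
        tables = {tp: de_frame([1.5], ["g"]) for tp in (10, 15, 21)}
        with pytest.raises(ValueError):
            combine_scores(tables)

    def test_scores_finite_at_zero_fdr(self):
        tables = {tp: de_frame([0.0], ["g"]) for tp in (10, 15, 21)}
        assert np.isfinite(combine_scores(tables)["g"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        fdr=st.floats(min_value=1e-10, max_value=1.0),
        lower=st.floats(min_value=0.1, max_value=0.999),
    )
    def test_monotone_in_each_fdr(self, fdr, lower):
        base = {tp: de_frame([fdr], ["g"]) for tp in (10, 15, 21)}
        s0 = combine_scores(base)["g"]
        improved = dict(base)
        improved[10] = de_frame([fdr * lower], ["g"])
        s1 = combine_scores(improved)["g"]
        assert s1 >= s0 - 1e-12


class TestMWCS:
    def test_path_linker_example(self):
        # prizes 4, -1, 4: spanning the linker beats any single terminal
        g = nx.Graph([("A", "B"), ("B", "C")])
        nodes, net = mwcs_heuristic(g, {"A": 4.0, "B": -1.0, "C": 4.0})
        assert nodes == {"A", "B", "C"}
        assert net == pytest.approx(7.0)

    def test_expensive_linker_not_worth_it(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        nodes, net = mwcs_heuristic(g, {"A": 4.0, "B": -10.0, "C": 4.0})
        assert net == pytest.approx(4.0)
        assert len(nodes) == 1

    @pytest.mark.parametrize("seed", range(50))
    def test_near_optimal_on_random_graphs(self, seed):
        g = random_graph(10, 0.3, seed)
        rng = np.random.default_rng(seed + 1000)
        w = {v: float(rng.normal(0, 2)) for v in sorted(g.nodes())}
        opt_net, _ = brute_mwcs(g, w)
        _, net = mwcs_heuristic(g, w)
        if opt_net > 0:
            assert net >= 0.9 * opt_net - 1e-9

    def test_optimal_on_trees(self):
        hits = 0
        total = 0
        for seed in range(50):
            t = nx.relabel_nodes(nx.random_labeled_tree(10, seed=seed),
                                 lambda i: f"t{i:02d}")
            rng = np.random.default_rng(seed + 2000)
            w = {v: float(rng.normal(0, 2)) for v in sorted(t.nodes())}
            opt_net, _ = brute_mwcs(t, w)
            _, net = mwcs_heuristic(t, w)
            total += 1
            hits += abs(net - opt_net) < 1e-9
        assert hits / total >= 0.9


class TestFindSubnetwork:
    def test_uniform_scores_return_whole_connected_network(self):
        g = nx.relabel_nodes(nx.connected_watts_strogatz_graph(40, 4, 0.2, seed=1),
                             lambda i: f"n{i:02d}")
        scores = pd.Series(10.0, index=sorted(g.nodes()))
        result = find_subnetwork(g, scores, size_range=(30, 60))
        assert set(result.nodes) == set(g.nodes())
        assert result.size_in_range

    def test_result_is_connected_with_no_negative_leaves(self):
        for seed in range(5):
            g = random_graph(30, 0.15, seed + 10)
            rng = np.random.default_rng(seed)
            scores = pd.Series(
                rng.exponential(1.0, size=30), index=sorted(g.nodes())
            )
            result = find_subnetwork(g, scores, size_range=(5, 15))
            if len(result) == 0:
                continue
            assert nx.is_connected(result.graph)
            # no negative-prize leaf: every sub-threshold node is interior
            for v in result.graph.nodes():
                if result.scores[v] < result.threshold:
                    assert result.graph.degree(v) >= 2

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            find_subnetwork(nx.Graph(), pd.Series(dtype=float))

    def test_all_zero_scores_give_empty_result(self):
        g = nx.Graph([("A", "B")])
        result = find_subnetwork(g, pd.Series({"A": 0.0, "B": 0.0}))
        assert len(result) == 0 and not result.size_in_range

    def test_deterministic(self):
        g = random_graph(25, 0.2, 3)
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.exponential(1.0, size=25),
                           index=sorted(g.nodes()))
        a = find_subnetwork(g, scores, size_range=(5, 15))
        b = find_subnetwork(g, scores, size_range=(5, 15))
        assert a.nodes == b.nodes and a.threshold == b.threshold
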