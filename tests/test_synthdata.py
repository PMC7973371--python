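"""Synthetic data generator: planted structure, determinism, null calibration."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import myonet
from myonet import (
    GROUP_LABELS,
    SimConfig,
    adjust_bh,
    simulate_counts,
    simulate_drug_table,
    simulate_module_scores,
    simulate_network_and_pathways,
)
from myonet.synthdata import GROUP_EFFECTS, ConfigurationError


class TestSimConfig:
    def test_group_sizes_exceeding_genes_rejected(self):
        with pytest.raises(ConfigurationError, match="exceeds"):
            SimConfig(n_genes=10, group_sizes={"EPi": 11})

    def test_unknown_group_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown group"):
            SimConfig(group_sizes={"XXi": 1})

    @pytest.mark.parametrize(
        "kwargs", [{"nb_dispersion": 0.0}, {"effect_log2fc": -1},
                   {"n_replicates": 1}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)


class TestSimulateCounts:
    def test_no_planted_effects_gives_all_null_labels(self):
        counts, truth = simulate_counts(SimConfig(n_genes=50, seed=1))
        assert set(truth.labels.values()) == {"null"}
        assert (counts.counts.to_numpy() >= 0).all()

    def test_same_seed_bit_identical(self):
        config = SimConfig(n_genes=100, group_sizes={"EPi": 10}, seed=42)
        a, _ = simulate_counts(config)
        b, _ = simulate_counts(config)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_different_seed_differs(self):
        a, _ = simulate_counts(SimConfig(n_genes=100, seed=1))
        b, _ = simulate_counts(SimConfig(n_genes=100, seed=2))
        assert not a.counts.equals(b.counts)

    def test_planted_means_follow_group_rules(self):
        """Empirical disease/control mean ratios match the planted ±log2fc
        exactly at the timepoints each group's rule prescribes."""
        config = SimConfig(
            n_genes=400,
            group_sizes={g: 40 for g in GROUP_LABELS},
            effect_log2fc=2.0,
            nb_dispersion=0.05,
            n_replicates=60,  # many replicates to pin down the means
            libsize_factor_range=(1.0, 1.0),
            seed=7,
        )
        counts, truth = simulate_counts(config)
        for group, effects in GROUP_EFFECTS.items():
            genes = truth.genes_in(group)[:10]
            for tp_index, tp in enumerate(config.timepoints):
                dis = counts.counts.loc[genes, counts.samples_at(tp, "disease")]
                con = counts.counts.loc[genes, counts.samples_at(tp, "control")]
                ratio = np.log2(dis.mean(axis=1) / con.mean(axis=1))
                expected = 2.0 * effects.get(tp_index, 0)
                assert ratio.mean() == pytest.approx(expected, abs=0.25)

    def test_null_false_call_rate_controlled(self):
        """Two-sample test over ≥1000 null genes at FDR 0.01 yields ≤2.5%
        calls (binomial tolerance)."""
        config = SimConfig(n_genes=1500, seed=11)
        counts, _ = simulate_counts(config)
        rates = []
        for tp in (10, 15, 21):
            dis = counts.counts[counts.samples_at(tp, "disease")].to_numpy()
            con = counts.counts[counts.samples_at(tp, "control")].to_numpy()
            _, p = stats.ttest_ind(np.log1p(dis), np.log1p(con), axis=1)
            rates.append((adjust_bh(p) < 0.01).mean())
        assert np.mean(rates) <= 0.025

    def test_recovery_monotone_in_effect_size(self):
        """Planted-gene recovery at log2fc=3 is at least that at log2fc=1."""
        rates = {}
        for lfc in (1.0, 3.0):
            hits = total = 0
            for seed in (0, 1, 2):
                config = SimConfig(
                    n_genes=600, group_sizes={"EPi": 50}, effect_log2fc=lfc,
                    seed=seed,
                )
                counts, truth = simulate_counts(config)
                de = myonet.run_differential(myonet.filter_low_counts(counts))
                groups = myonet.assign_groups(myonet.call_patterns(de))
                epi = set(truth.genes_in("EPi"))
                hits += sum(groups.get(g) == "EPi" for g in epi)
                total += len(epi)
            rates[lfc] = hits / total
        assert rates[3.0] >= rates[1.0]


class TestSimulateNetwork:
    def test_single_pathway_identity(self):
        network, collection, _ = simulate_network_and_pathways(
            1, 5, 0.0, 0, seed=0
        )
        assert set(network.nodes()) == set(collection.sets[0].genes)

    def test_zero_overlap_gives_disjoint_components(self):
        network, _, _ = simulate_network_and_pathways(2, 10, 0.0, 0, seed=0)
        assert nx.number_connected_components(network) >= 2

    def test_planted_module_is_connected_and_recorded(self):
        network, _, truth = simulate_network_and_pathways(5, 20, 0.3, 15, seed=3)
        assert len(truth.module_genes) == 15
        assert nx.is_connected(network.subgraph(truth.module_genes))

    def test_impossible_module_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_network_and_pathways(2, 5, 0.0, 11, seed=0)

    def test_pathways_connected_internally(self):
        _, collection, _ = simulate_network_and_pathways(4, 15, 0.2, 0, seed=5)
        network, _, _ = simulate_network_and_pathways(4, 15, 0.2, 0, seed=5)
        for gset in collection:
            sub = network.subgraph(gset.genes)
            assert nx.is_connected(sub)


class TestSimulateModuleScores:
    def test_module_scores_separate_from_background(self):
        network, _, truth = simulate_network_and_pathways(5, 20, 0.3, 10, seed=2)
        scores = simulate_module_scores(network, truth.module_genes, seed=2)
        module = scores[truth.module_genes]
        background = scores.drop(truth.module_genes)
        assert module.min() >= 3.0
        assert background.max() <= 0.5


class TestSimulateDrugTable:
    def test_all_approved_when_fraction_one(self):
        table = simulate_drug_table(["a", "b", "c"], fraction_approved=1.0, seed=0)
        live = table[~table["withdrawn"] & (table["indication"] != "duplicated indication")]
        assert (live["max_phase"] == 4).all()

    def test_deterministic(self):
        a = simulate_drug_table(["a", "b"], seed=5)
        b = simulate_drug_table(["a", "b"], seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_withdrawn_and_duplicate_rows(self):
        table = simulate_drug_table(["x", "y"], seed=1)
        assert table["withdrawn"].any()
        dup = table[table["indication"] == "duplicated indication"]
        assert sorted(dup["max_phase"]) == [2, 4]

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_drug_table([])


class TestFixtureGraphs:
    def test_expected_shapes(self, fixture_graphs):
        star5 = fixture_graphs["star5"]
        path3 = fixture_graphs["path3"]
        barbell9 = fixture_graphs["barbell9"]
        assert (star5.number_of_nodes(), star5.number_of_edges()) == (5, 4)
        assert (path3.number_of_nodes(), path3.number_of_edges()) == (3, 2)
        # two 4-cliques plus a bridging vertex: 2*C(4,2) + 2 = 14 edges
        assert (barbell9.number_of_nodes(), barbell9.number_of_edges()) == (9, 14)
        for g in fixture_graphs.values():
            assert not any(u == v for u, v in g.edges())
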