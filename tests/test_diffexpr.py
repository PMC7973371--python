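"""Count filtering, BH adjustment, and the negative-binomial Wald test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myonet import (
    CountsTable,
    SimConfig,
    adjust_bh,
    filter_low_counts,
    simulate_counts,
    size_factors,
)
from myonet.diffexpr import test_differential as nb_wald_test


def bh_reference(p):
    """Independent closed form: adj_i = min_{j>=i} p_(j) * n / j, clipped."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (p[order] * n / np.arange(1, n + 1))[::-1]
    )[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj_sorted, 0, 1)
    return out


def make_counts(matrix, conditions, timepoint=10):
    matrix = np.asarray(matrix)
    genes = [f"g{i}" for i in range(matrix.shape[0])]
    sample_ids = [f"s{j}" for j in range(matrix.shape[1])]
    reps = {}
    rows = []
    for sid, cond in zip(sample_ids, conditions):
        reps[cond] = reps.get(cond, 0) + 1
        rows.append((sid, cond, timepoint, reps[cond]))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "condition", "timepoint", "replicate"]
    ).set_index("sample_id")
    counts = pd.DataFrame(np.asarray(matrix), index=pd.Index(genes, name="gene"),
                          columns=sample_ids)
    return CountsTable(counts, meta)


class TestCountsTable:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_counts([[5, -1, 2, 3]], ["disease"] * 2 + ["control"] * 2)

    def test_duplicate_gene_rejected(self, tiny_counts):
        counts = tiny_counts.counts.copy()
        counts.index = ["gA", "gA"]
        with pytest.raises(ValueError, match="duplicate"):
            CountsTable(counts, tiny_counts.samples)

    def test_sample_missing_from_sheet_named(self, tiny_counts):
        meta = tiny_counts.samples.drop(index="d10_disease_r1")
        with pytest.raises(ValueError, match="d10_disease_r1"):
            CountsTable(tiny_counts.counts, meta)


class TestFilterLowCounts:
    def test_all_zero_gene_removed(self):
        ct = make_counts(
            [[0] * 8, [20] * 8], ["disease"] * 4 + ["control"] * 4
        )
        kept = filter_low_counts(ct, min_count=10, min_samples=4)
        assert kept.genes == ["g1"]

    @pytest.mark.parametrize("n_pass, kept", [(4, True), (3, False)])
    def test_boundary_at_smallest_group_size(self, n_pass, kept):
        row = [10] * n_pass + [0] * (8 - n_pass)
        ct = make_counts([row], ["disease"] * 4 + ["control"] * 4)
        result = filter_low_counts(ct, min_count=10, min_samples=4)
        assert (len(result.genes) == 1) is kept

    def test_zero_threshold_keeps_everything(self, tiny_counts):
        assert filter_low_counts(tiny_counts, min_count=0).genes == tiny_counts.genes

    def test_default_min_samples_is_smallest_group(self, tiny_counts):
        assert tiny_counts.smallest_group_size() == 2
        # gene passing in exactly 2 samples is kept under the default
        counts = tiny_counts.counts.copy()
        counts.loc["gA"] = 0
        counts.loc["gA", ["d10_disease_r1", "d10_disease_r2"]] = 10
        ct = CountsTable(counts, tiny_counts.samples)
        assert "gA" in filter_low_counts(ct).genes

    def test_empty_result_allowed(self, tiny_counts):
        assert filter_low_counts(tiny_counts, min_count=10**9).counts.shape[0] == 0


class TestAdjustBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_known_values(self, p, expected):
        assert adjust_bh(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_closed_form_reference(self, p):
        assert adjust_bh(p) == pytest.approx(bh_reference(p))

    def test_fdr_at_least_raw_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        assert (adjust_bh(p) >= p - 1e-12).all()


class TestSizeFactors:
    def test_pure_scaling_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.integers(50, 500, size=100).astype(float)
        factors = np.array([0.5, 1.0, 2.0, 1.5])
        counts = pd.DataFrame(
            np.round(base[:, None] * factors[None, :]).astype(int),
            columns=list("abcd"),
        )
        sf = size_factors(counts)
        ratio = sf / sf["b"]
        assert ratio.to_numpy() == pytest.approx(factors / 1.0, rel=0.05)


class TestDifferential:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(2)
        block = rng.poisson(200, size=(50, 4))
        ct = make_counts(np.hstack([block, block]),
                         ["disease"] * 4 + ["control"] * 4)
        table = nb_wald_test(ct, 10)
        assert table["log2fc"].to_numpy() == pytest.approx(0.0)
        assert (table["call"] == "ns").all()

    def test_missing_condition_rejected(self):
        ct = make_counts([[5] * 4], ["disease"] * 4)
        with pytest.raises(ValueError, match="replicates"):
            nb_wald_test(ct, 10)

    def test_planted_effect_power(self):
        """A 8-fold induced gene at moderate depth is nearly always called."""
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            r = 1 / 0.1
            control = rng.negative_binomial(r, r / (r + 500.0), size=(1, 4))
            disease = rng.negative_binomial(r, r / (r + 4000.0), size=(1, 4))
            null = rng.negative_binomial(r, r / (r + 300.0), size=(400, 8))
            matrix = np.vstack([np.hstack([disease, control]), null])
            ct = make_counts(matrix, ["disease"] * 4 + ["control"] * 4)
            table = nb_wald_test(ct, 10)
            hits += table.loc[table["gene"] == "g0", "call"].iloc[0] == "induced"
        assert hits / n_rep >= 0.95

    def test_null_type_i_error_controlled(self):
        """On null data, ≤2.5% of genes are called at FDR 0.01."""
        rates = []
        for seed in range(5):
            config = SimConfig(n_genes=2000, seed=seed)
            counts, _ = simulate_counts(config)
            table = nb_wald_test(counts, 10)
            rates.append((table["call"] != "ns").mean())
        assert np.mean(rates) <= 0.025

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(4)
        matrix = rng.poisson(150, size=(30, 8))
        ct = make_counts(matrix, ["disease"] * 4 + ["control"] * 4)
        t1 = nb_wald_test(ct, 10).set_index("gene")
        perm = rng.permutation(30)
        ct2 = CountsTable(ct.counts.iloc[perm], ct.samples)
        t2 = nb_wald_test(ct2, 10).set_index("gene")
        pd.testing.assert_frame_equal(
            t1.sort_index(), t2.sort_index(), check_like=True
        )
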