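"""Wilcoxon rank-sum (asymptotic and exact), fold-change convention, BH
adjustment, the per-cell-type contrast, DEG filtering, and marker detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from flexde import (
    DEGFilter,
    wilcoxon_rank_sum,
    log2_fold_change,
    bh_adjust,
    de_contrast_by_celltype,
    filter_degs,
    deg_summary,
    find_cluster_markers,
    lognormalize,
)
from conftest import make_adata


def perm_oracle_p(x, y):
    """Independent exact two-sided rank-sum p via scipy's permutation machinery.

    Singleton groups (unsupported by scipy) reduce to the uniform
    distribution of a single rank over the pooled ranking.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if min(len(x), len(y)) == 1:
        if len(y) == 1:  # p is symmetric under group swap
            x, y = y, x
        ranks = stats.rankdata(np.concatenate([x, y]))
        mu = (len(ranks) + 1) / 2.0
        return float(np.mean(np.abs(ranks - mu) >= abs(ranks[0] - mu) - 1e-9))

    # Two-sided criterion |W - E[W]|: with ties the permutation distribution
    # of W is not symmetric, so this must be the enumerated statistic itself.
    def centered_ranksum(a, b, axis):
        pooled = np.concatenate([a, b], axis=axis)
        r = stats.rankdata(pooled, axis=axis)
        n = np.shape(a)[axis]
        mu = n * (pooled.shape[axis] + 1) / 2.0
        return np.abs(np.take(r, np.arange(n), axis=axis).sum(axis=axis) - mu)

    res = stats.permutation_test(
        (x, y),
        centered_ranksum,
        permutation_type="independent",
        n_resamples=np.inf,
        alternative="greater",
        vectorized=True,
    )
    return float(res.pvalue)


class TestWilcoxon:
    def test_identical_groups_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 2, 3], [3, 2, 1, 2])
        assert p == 1.0

    def test_small_example_matches_enumeration(self):
        # 20 ways to choose 3 ranks of 6; only the two extreme assignments
        # reach |W - E[W]| = 4.5, so the exact two-sided p is 2/20.
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], method="exact")
        assert p == pytest.approx(0.1)

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(0)
        x, y = rng.poisson(2, 9), rng.poisson(3, 5)
        assert wilcoxon_rank_sum(x, y)[1] == pytest.approx(wilcoxon_rank_sum(y, x)[1])
        assert wilcoxon_rank_sum(x, y, method="exact")[1] == pytest.approx(
            wilcoxon_rank_sum(y, x, method="exact")[1]
        )

    def test_asymptotic_matches_scipy_convention(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=40), rng.normal(0.5, size=30)
        _, p = wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, use_continuity=False, method="asymptotic")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("with_ties", [False, True])
    def test_exact_mode_matches_permutation_oracle(self, with_ties):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n, m = rng.integers(2, 7, size=2)
            if with_ties:
                x, y = rng.integers(0, 4, n), rng.integers(0, 4, m)
            else:
                x, y = rng.normal(size=n), rng.normal(size=m)
            _, p = wilcoxon_rank_sum(x, y, method="exact")
            assert p == pytest.approx(perm_oracle_p(x, y), abs=1e-9)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])


class TestLog2FoldChange:
    def test_pseudocount_examples(self):
        # group means of expm1(values): 1 vs 0 -> log2(2/1) = 1
        lfc, *_ = log2_fold_change(np.log1p([1.0, 1.0]), [0.0, 0.0])
        assert lfc == pytest.approx(1.0)
        lfc, *_ = log2_fold_change(np.log1p([3.0, 3.0]), np.log1p([1.0, 1.0]))
        assert lfc == pytest.approx(1.0)

    def test_equal_means_give_zero(self):
        v = np.log1p([2.0, 0.0, 4.0])
        lfc, px, py, mx, my = log2_fold_change(v, v[::-1])
        assert lfc == 0.0 and mx == pytest.approx(my)

    def test_detection_fractions(self):
        _, px, py, *_ = log2_fold_change(np.log1p([1.0, 0.0, 2.0, 0.0]), np.log1p([1.0]))
        assert px == 0.5 and py == 1.0


def bh_oracle(p):
    """Step-up formula applied literally on the sorted vector."""
    p = np.asarray(p, float)
    order = np.argsort(p, kind="mergesort")
    m = len(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBHAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_clamped(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_sorted_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


def two_type_adata(rng, n_genes=60, n_per=50):
    counts = rng.negative_binomial(2, 2 / 3.0, size=(n_genes, 4 * n_per))
    cond = ["infected"] * n_per + ["uninfected"] * n_per
    adata = make_adata(
        counts,
        [f"g{i}" for i in range(n_genes)],
        [f"c{i}" for i in range(4 * n_per)],
        condition=cond * 2,
        cell_type=["ctA"] * 2 * n_per + ["ctB"] * 2 * n_per,
    )
    return lognormalize(adata)


class TestDEContrast:
    def test_records_consistent_with_direct_computation(self, small_norm):
        de = de_contrast_by_celltype(small_norm)
        assert not de.empty
        row = de.iloc[17]
        X = small_norm.X.toarray()
        obs = small_norm.obs
        gi = small_norm.var_names.get_loc(row.gene_id)
        m1 = (obs.cell_type == row.cell_type) & (obs.condition == "infected")
        m2 = (obs.cell_type == row.cell_type) & (obs.condition == "uninfected")
        lfc, p1, p2, mx, my = log2_fold_change(X[m1.to_numpy(), gi], X[m2.to_numpy(), gi])
        _, p = wilcoxon_rank_sum(X[m1.to_numpy(), gi], X[m2.to_numpy(), gi])
        assert row.log2fc == pytest.approx(lfc)
        assert (row.pct_1, row.pct_2) == (pytest.approx(p1), pytest.approx(p2))
        assert row.p_value == pytest.approx(p, abs=1e-10)
        assert row.p_adjust >= row.p_value

    def test_prefilter_excludes_low_detection_and_small_fold_change(self, small_norm):
        de = de_contrast_by_celltype(small_norm, DEGFilter())
        assert (np.maximum(de.pct_1, de.pct_2) >= 0.25).all()
        assert (de.log2fc.abs() >= 0.25).all()
        permissive = de_contrast_by_celltype(
            small_norm, DEGFilter(min_abs_log2fc=0.0, prefilter_min_pct_either=0.0)
        )
        dropped = permissive.merge(de, on=["gene_id", "cell_type"], how="left", indicator=True)
        only_perm = dropped[dropped._merge == "left_only"]
        assert (
            (np.maximum(only_perm.pct_1_x, only_perm.pct_2_x) < 0.25)
            | (only_perm.log2fc_x.abs() < 0.25)
        ).all()

    def test_bh_family_is_within_cell_type(self, small_norm):
        de = de_contrast_by_celltype(small_norm)
        for _, grp in de.groupby("cell_type"):
            np.testing.assert_allclose(
                grp.p_adjust.to_numpy(), bh_adjust(grp.p_value.to_numpy()), atol=1e-12
            )

    def test_condition_swap_negates_lfc_and_preserves_p(self):
        norm = two_type_adata(np.random.default_rng(11))
        de = de_contrast_by_celltype(norm, DEGFilter(min_abs_log2fc=0, prefilter_min_pct_either=0))
        swapped = norm.copy()
        swapped.uns["layer"] = "normalized"
        swapped.obs["condition"] = np.where(
            norm.obs.condition == "infected", "uninfected", "infected"
        )
        de_sw = de_contrast_by_celltype(swapped, DEGFilter(min_abs_log2fc=0, prefilter_min_pct_either=0))
        merged = de.merge(de_sw, on=["gene_id", "cell_type"])
        np.testing.assert_allclose(merged.log2fc_x, -merged.log2fc_y, atol=1e-12)
        np.testing.assert_allclose(merged.p_value_x, merged.p_value_y, atol=1e-12)

    def test_missing_condition_stratum_skipped(self, caplog):
        rng = np.random.default_rng(3)
        counts = rng.poisson(2, size=(20, 30))
        adata = make_adata(
            counts, [f"g{i}" for i in range(20)], [f"c{i}" for i in range(30)],
            condition=["infected"] * 30, cell_type=["ctA"] * 30,
        )
        de = de_contrast_by_celltype(lognormalize(adata))
        assert de.empty


class TestFilterDEGs:
    RECORDS = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "cell_type": "ctA",
            "log2fc": [0.3, 0.25, 0.5],
            "p_value": [0.04, 0.049, 0.5],
            "p_adjust": [0.1, 0.1, 0.6],
            "pct_1": [0.5, 0.25, 0.9],
            "pct_2": [0.2, 0.25, 0.9],
        }
    )

    def test_both_population_detection_rule(self):
        kept = filter_degs(self.RECORDS)
        assert "g1" not in kept.gene_id.tolist()  # pct_2 = 0.2 < 0.25

    def test_boundaries_inclusive_for_lfc_and_pct_exclusive_for_p(self):
        kept = filter_degs(self.RECORDS)
        assert kept.gene_id.tolist() == ["g2"]
        at_p = self.RECORDS.assign(p_value=[0.04, 0.05, 0.5])
        assert filter_degs(at_p).empty

    def test_tightening_lfc_threshold_is_monotone(self, small_norm):
        de = de_contrast_by_celltype(small_norm)
        counts = [
            len(filter_degs(de, DEGFilter(min_abs_log2fc=t))) for t in (0.25, 0.5, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_summary_counts_directions(self):
        degs = pd.DataFrame(
            {"cell_type": ["a", "a", "b"], "log2fc": [1.0, -2.0, 0.5]}
        )
        out = deg_summary(degs).set_index("cell_type")
        assert out.loc["a"].tolist() == [1, 1] and out.loc["b"].tolist() == [1, 0]


def test_power_on_strong_detectable_planted_effects():
    """At 150 cells per group, >=90% of planted effects with |log2FC| >= 1
    survive the full DEG filter cascade when baseline expression is high
    enough that the 25%-detection rule is not limiting."""
    from flexde import SimConfig, simulate_dataset

    cfg = SimConfig(
        n_genes=800, n_cell_types=6, cells_per_type_per_condition=150,
        baseline_logmean_mu=1.2, baseline_logmean_sd=0.8,
        frac_affected_genes=0.2, coupling_beta=1.5, effect_noise_sd=0.1, seed=17,
    )
    adata, _, truth = simulate_dataset(cfg)
    degs = filter_degs(de_contrast_by_celltype(lognormalize(adata)))
    strong = truth.true_log2fc.stack().loc[lambda s: s.abs() >= 1.0].reset_index()
    strong.columns = ["gene_id", "cell_type", "true_log2fc"]
    assert len(strong) > 100
    merged = strong.merge(
        degs[["gene_id", "cell_type"]], on=["gene_id", "cell_type"],
        how="left", indicator=True,
    )
    assert (merged._merge == "both").mean() >= 0.90


class TestMarkers:
    def test_exclusive_marker_reported_once_and_positive_only(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(2, size=(30, 80))
        counts[0, :40] += 20   # strong marker of cluster A
        counts[0, 40:] = 0
        counts[1, :40] = 0     # downregulated in A
        counts[1, 40:] += 20
        adata = make_adata(
            counts, [f"g{i}" for i in range(30)], [f"c{i}" for i in range(80)],
            condition="infected", cell_type=["A"] * 40 + ["B"] * 40,
        )
        markers = find_cluster_markers(lognormalize(adata))
        g0 = markers[markers.gene_id == "g0"]
        assert g0.cell_type.tolist() == ["A"]
        assert "g1" not in markers[markers.cell_type == "A"].gene_id.tolist()
        assert (markers.log2fc > 0).all()

    def test_identical_clusters_yield_chance_level_markers(self):
        rng = np.random.default_rng(8)
        counts = rng.negative_binomial(2, 0.4, size=(200, 160))
        adata = make_adata(
            counts, [f"g{i}" for i in range(200)], [f"c{i}" for i in range(160)],
            condition="infected", cell_type=["A"] * 80 + ["B"] * 80,
        )
        markers = find_cluster_markers(lognormalize(adata))
        sig = markers[markers.p_value < 0.05]
        assert len(sig) <= 0.15 * 200  # well below any real marker signal

    def test_single_cluster_rejected(self):
        adata = make_adata(np.ones((3, 4), dtype=int), list("abc"), list("wxyz"))
        with pytest.raises(ValueError, match="2 cell types"):
            find_cluster_markers(lognormalize(adata))
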