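import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossdeg.diffexp import (
    adjust_bh,
    call_degs,
    cluster_samples,
    estimate_dispersions,
    genewise_dispersions,
    nb_wald_test,
    size_factors,
)
from crossdeg.errors import DegenerateInputError, ValidationError
from crossdeg.simulate import nb_sample
from tests.conftest import make_count_matrix


def bh_oracle(p):
    """Literal step-up: find max i with p_(i) <= i*q/m, then adjust."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        val = min(prev, p[order[rank - 1]] * m / rank)
        adj[order[rank - 1]] = val
        prev = val
    return adj


class TestSizeFactors:
    def test_identical_samples_give_unity(self):
        cm = make_count_matrix(np.array([[5, 5], [9, 9], [2, 2]]))
        assert size_factors(cm).to_numpy() == pytest.approx([1.0, 1.0])

    def test_doubled_sample_hand_value(self):
        # sample 2 = 2 x sample 1 for all genes: median ratios are
        # (1/sqrt(2), sqrt(2)) against the geometric-mean reference
        base = np.array([[10], [40], [7], [100]])
        cm = make_count_matrix(np.hstack([base, 2 * base]))
        s = size_factors(cm).to_numpy()
        assert s == pytest.approx([1 / np.sqrt(2), np.sqrt(2)], rel=1e-12)

    def test_single_sample_is_one(self):
        cm = make_count_matrix(np.array([[3], [8]]), conditions=["control"])
        assert size_factors(cm).to_numpy() == pytest.approx([1.0])

    def test_geometric_mean_is_one(self, rng):
        y = rng.poisson(50.0, size=(200, 6))
        cm = make_count_matrix(y)
        s = size_factors(cm).to_numpy()
        assert np.prod(s) ** (1 / len(s)) == pytest.approx(1.0, rel=1e-12)

    def test_no_all_positive_gene_raises_without_fallback(self):
        cm = make_count_matrix(np.array([[0, 1], [1, 0]]))
        with pytest.raises(DegenerateInputError):
            size_factors(cm)


class TestDispersions:
    def test_poisson_counts_floor_median(self, rng):
        y = rng.poisson(rng.uniform(50, 500, 2000)[:, None], size=(2000, 6))
        cm = make_count_matrix(y)
        s = size_factors(cm)
        med = float(genewise_dispersions(cm, s).median())
        assert med < 0.01  # true alpha = 0; half the MoM estimates hit the floor

    def test_nb_dispersion_recovered(self, rng):
        mu = rng.uniform(100, 500, 2000)
        lam = rng.gamma(1 / 0.2, 0.2 * mu[:, None], size=(2000, 6))
        cm = make_count_matrix(rng.poisson(lam))
        s = size_factors(cm)
        med = float(genewise_dispersions(cm, s).median())
        assert 0.1 <= med <= 0.4

    def test_constant_gene_hits_floor(self):
        y = np.array([[5, 5, 5, 5], [1, 2, 3, 4]])
        cm = make_count_matrix(y)
        s = pd.Series(np.ones(4), index=cm.sample_ids)
        d = genewise_dispersions(cm, s)
        assert d.iloc[0] == pytest.approx(1e-8)

    def test_trend_tracks_constant_dispersion(self, rng):
        mu = rng.uniform(50, 500, 2000)
        lam = rng.gamma(1 / 0.1, 0.1 * mu[:, None], size=(2000, 6))
        cm = make_count_matrix(rng.poisson(lam))
        s = size_factors(cm)
        d = estimate_dispersions(cm, s, method="trend")
        assert 0.05 <= float(d.median()) <= 0.2


class TestWald:
    def test_identical_groups_are_null(self):
        block = np.array([[10, 20, 30], [100, 110, 90]])
        cm = make_count_matrix(np.hstack([block, block]))
        s = pd.Series(np.ones(6), index=cm.sample_ids)
        d = pd.Series([0.1, 0.1], index=cm.gene_ids)
        t = nb_wald_test(cm, s, d)
        assert t["log2fc"].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-8)
        assert (t["pvalue"] > 0.999).all()

    def test_zero_in_both_groups_gives_na(self):
        y = np.array([[0, 0, 0, 0, 0, 0], [10, 12, 9, 11, 10, 13]])
        cm = make_count_matrix(y)
        s = pd.Series(np.ones(6), index=cm.sample_ids)
        d = pd.Series([0.1, 0.1], index=cm.gene_ids)
        t = nb_wald_test(cm, s, d)
        assert np.isnan(t.loc["g0", "pvalue"]) and np.isnan(t.loc["g0", "log2fc"])

    def test_one_group_zero_gets_sentinel(self):
        y = np.array([[0, 0, 0, 10, 12, 9], [10, 12, 9, 0, 0, 0],
                      [5, 6, 7, 5, 6, 7]])
        cm = make_count_matrix(y)
        s = pd.Series(np.ones(6), index=cm.sample_ids)
        d = pd.Series([0.1] * 3, index=cm.gene_ids)
        t = nb_wald_test(cm, s, d)
        assert t.loc["g0", "log2fc"] == 30.0 and np.isnan(t.loc["g0", "pvalue"])
        assert t.loc["g1", "log2fc"] == -30.0
        up, down = call_degs(t)
        assert "g0" not in up and "g1" not in down

    def test_condition_swap_negates_beta(self, rng):
        y = rng.poisson(rng.uniform(50, 200, 50)[:, None], size=(50, 6))
        cm1 = make_count_matrix(y, conditions=["control"] * 3 + ["treated"] * 3)
        cm2 = make_count_matrix(y, conditions=["treated"] * 3 + ["control"] * 3)
        s = pd.Series(np.ones(6), index=cm1.sample_ids)
        d = pd.Series([0.1] * 50, index=cm1.gene_ids)
        t1 = nb_wald_test(cm1, s, d)
        t2 = nb_wald_test(cm2, s, d)
        assert t1["log2fc"].to_numpy() == pytest.approx(
            -t2["log2fc"].to_numpy(), abs=1e-6
        )
        u1, d1 = call_degs(t1)
        u2, d2 = call_degs(t2)
        assert u1 == d2 and d1 == u2

    def test_planted_effect_recovered(self, rng):
        # 500 genes, planted log2FC = 1.5 at mean ~100-400: beta-hat unbiased
        mu = rng.uniform(100, 400, 500)
        mean = mu[:, None] * np.array([1, 1, 1, 2**1.5, 2**1.5, 2**1.5])[None, :]
        y = rng.poisson(rng.gamma(10.0, 0.1 * mean))
        cm = make_count_matrix(y)
        s = pd.Series(np.ones(6), index=cm.sample_ids)
        d = pd.Series([0.1] * 500, index=cm.gene_ids)
        t = nb_wald_test(cm, s, d)
        assert float(t["log2fc"].mean()) == pytest.approx(1.5, abs=0.2)


class TestBH:
    def test_single_p(self):
        assert adjust_bh([0.03]) == pytest.approx([0.03])

    def test_hand_example(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3 -> monotone -> all 0.03
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_na_propagates_and_excluded_from_m(self):
        out = adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx(bh_oracle([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_matches_literal_step_up_oracle(self, pvals):
        assert adjust_bh(pvals) == pytest.approx(bh_oracle(pvals), abs=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            ref = multipletests(p, method="fdr_bh")[1]
            assert adjust_bh(p) == pytest.approx(ref, abs=1e-12)


class TestCallDegs:
    def _table(self, log2fc, padj):
        return pd.DataFrame(
            {"log2fc": log2fc, "padj": padj},
            index=pd.Index([f"g{i}" for i in range(len(padj))], name="gene_id"),
        )

    def test_threshold_arithmetic(self):
        t = self._table([1.0, 0.5, -1.0, 0.59], [0.01, 0.001, 0.01, 0.049])
        up, down = call_degs(t)
        assert up == {"g0", "g3"}  # 0.59 >= log2(1.5) ~ 0.585
        assert down == {"g2"}
        assert "g1" not in up | down  # |0.5| < log2(1.5)

    def test_boundary_padj_excluded(self):
        # adjusted p exactly at alpha is NOT a DEG (strict inequality)
        t = self._table([2.0], [0.05])
        up, down = call_degs(t)
        assert not up and not down

    def test_gene_order_invariance(self):
        t = self._table([1.0, -2.0, 3.0], [0.01, 0.02, 0.001])
        up1, down1 = call_degs(t)
        up2, down2 = call_degs(t.iloc[::-1])
        assert up1 == up2 and down1 == down2


class TestClustering:
    def test_duplicated_samples_merge_first_at_zero(self, rng):
        y = rng.poisson(100.0, size=(50, 4))
        y = np.hstack([y, y[:, [0]]])  # 5th sample duplicates the 1st
        cm = make_count_matrix(y, conditions=["control"] * 3 + ["treated"] * 2)
        s = pd.Series(np.ones(5), index=cm.sample_ids)
        tree = cluster_samples(cm, s)
        z = tree.linkage_matrix
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        merged = {int(z[0, 0]), int(z[0, 1])}
        assert {tree.labels[i] for i in merged} == {"s0", "s4"}

    def test_sample_order_invariance(self, rng):
        y = rng.poisson(rng.uniform(20, 200, 60)[:, None], size=(60, 6))
        cm1 = make_count_matrix(y)
        perm = [3, 0, 5, 1, 4, 2]
        cm2 = make_count_matrix(
            y[:, perm],
            sample_ids=[f"s{j}" for j in perm],
            conditions=[cm1.meta["condition"].iloc[j] for j in perm],
        )
        s1 = pd.Series(np.ones(6), index=cm1.sample_ids)
        s2 = pd.Series(np.ones(6), index=cm2.sample_ids)
        t1 = cluster_samples(cm1, s1)
        t2 = cluster_samples(cm2, s2)
        assert t1.to_newick() == t2.to_newick()

    def test_constant_sample_raises_with_name(self):
        y = np.array([[1, 5, 7], [1, 9, 2], [1, 4, 4]])
        cm = make_count_matrix(y, conditions=["control", "control", "treated"])
        s = pd.Series(np.ones(3), index=cm.sample_ids)
        with pytest.raises(DegenerateInputError, match="s0"):
            cluster_samples(cm, s)

    def test_conditions_separate_with_strong_effects(self, rng):
        from crossdeg.simulate import SynthConfig, simulate_counts
        from crossdeg.diffexp import size_factors as sf

        cfg = SynthConfig(seed=11, n_genes=500, n_orthologs=400,
                          planted_quadrant_counts=(30, 30, 30, 30),
                          planted_specific_counts=(30, 30, 20, 20),
                          planted_effect_log2fc=3.0, dispersion=0.05)
        cm_a, _, _, _ = simulate_counts(cfg)
        tree = cluster_samples(cm_a, sf(cm_a))
        left, right = tree.first_bipartition()
        conds = {frozenset(cm_a.condition_of(x) for x in side) for side in (left, right)}
        assert conds == {frozenset({"control"}), frozenset({"treated"})}


class TestTypeIError:
    def test_null_simulation_calibrated(self):
        """Raw p-values behave uniformly on null NB data (single seed)."""
        from scipy import stats
        from crossdeg.simulate import SynthConfig, simulate_counts

        cfg = SynthConfig(seed=5, planted_effect_log2fc=0.0)
        cm, _, _, truth = simulate_counts(cfg)
        assert not truth.up_a and not truth.down_b  # zero effect -> empty truth
        s = size_factors(cm)
        d = estimate_dispersions(cm, s)
        t = nb_wald_test(cm, s, d)
        p = t["pvalue"].dropna().to_numpy()
        frac = float((p < 0.05).mean())
        assert 0.05 - 0.015 <= frac <= 0.05 + 0.015
        assert stats.kstest(p, "uniform").pvalue > 0.01
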