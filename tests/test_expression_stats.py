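import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosstype.expression_stats import (
    SsgseaConfig,
    bh_adjust,
    correlation_screen,
    nb_wald_de,
    size_factors,
    ssgsea_matrix,
    ssgsea_score,
    subgroup_crosstab,
)

from conftest import nb_two_group


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        col = pd.Series([10, 20, 5, 100])
        df = pd.DataFrame({"a": col, "b": col, "c": col})
        np.testing.assert_allclose(size_factors(df), 1.0)

    def test_doubled_column_doubled_factor(self, rng):
        base = rng.integers(5, 200, 50).astype(float)
        df = pd.DataFrame({"a": base, "b": base, "c": 2 * base})
        sf = size_factors(df)
        assert sf["c"] / sf["a"] == pytest.approx(2.0)

    def test_matches_loop_oracle(self, rng):
        df = pd.DataFrame(rng.integers(1, 500, (6, 4)).astype(float),
                          index=[f"g{i}" for i in range(6)], columns=list("abcd"))
        log_geo = np.log(df).mean(axis=1)
        expected = {c: float(np.exp(np.median(np.log(df[c]) - log_geo)))
                    for c in df.columns}
        sf = size_factors(df)
        for c in df.columns:
            assert sf[c] == pytest.approx(expected[c])

    def test_no_all_positive_gene_errors(self):
        df = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError):
            size_factors(df)


class TestNBWaldDE:
    def test_constant_gene_is_null(self, rng):
        counts, groups = nb_two_group(rng, n_genes=50, n_per_group=5)
        counts.iloc[0] = 42
        res = nb_wald_de(counts, groups)
        assert res.iloc[0]["log2_fc"] == 0.0
        assert res.iloc[0]["p"] == 1.0

    def test_label_swap_flips_fold_change(self, rng):
        counts, groups = nb_two_group(rng, n_genes=200, n_per_group=6,
                                      lfc=np.repeat([0.0, 2.0], 100))
        res = nb_wald_de(counts, groups)
        swapped = groups.map({"A": "Z", "B": "A"}).map({"Z": "B", "A": "A"})
        # relabel so that sorted level order reverses the contrast
        res2 = nb_wald_de(counts, groups.map({"A": "B", "B": "A"}))
        np.testing.assert_allclose(res["log2_fc"], -res2["log2_fc"], atol=1e-12)
        pd.testing.assert_series_equal(res["significant"], res2["significant"])

    def test_null_calibration_and_bh_control(self, rng):
        counts, groups = nb_two_group(rng, n_genes=2000, n_per_group=10)
        res = nb_wald_de(counts, groups)
        type1 = float((res.p < 0.05).mean())
        assert abs(type1 - 0.05) <= 0.02
        assert res.significant.sum() <= 2   # ~0 after BH

    def test_power_on_planted_fourfold(self, rng):
        lfc = np.zeros(2000)
        lfc[:200] = 2.0
        counts, groups = nb_two_group(rng, n_genes=2000, n_per_group=10, lfc=lfc)
        res = nb_wald_de(counts, groups)
        assert res.significant.iloc[:200].mean() >= 0.8

    def test_small_group_errors(self, rng):
        counts, groups = nb_two_group(rng, n_genes=20, n_per_group=2)
        with pytest.raises(ValueError):
            nb_wald_de(counts, groups)


class TestBHAdjust:
    def test_hand_worked_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    def test_matches_brute_force_definition(self, pvals):
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        running = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            running = min(running, p[i] * m / (rank_from_top + 1))
            q[i] = running
        np.testing.assert_allclose(bh_adjust(p), q, atol=1e-12)


class TestSsgsea:
    def test_four_gene_hand_enumeration_alpha_zero(self):
        """Sample (g1..g4) = (4,3,2,1); set = {g1} (the top gene); alpha 0.
        Walking the ranking: in-ECDF = (1,1,1,1), out-ECDF = (0,1/3,2/3,1);
        running differences 1 + 2/3 + 1/3 + 0 = 2."""
        sample = pd.Series([4.0, 3.0, 2.0, 1.0], index=["g1", "g2", "g3", "g4"])
        score = ssgsea_score(sample, {"g1"}, SsgseaConfig(alpha=0.0))
        assert score == pytest.approx(2.0)

    def test_monotone_transform_invariance_at_alpha_zero(self, rng):
        vals = pd.Series(rng.uniform(1, 10, 30), index=[f"g{i}" for i in range(30)])
        gene_set = set(vals.index[:7])
        cfg = SsgseaConfig(alpha=0.0)
        s1 = ssgsea_score(vals, gene_set, cfg)
        s2 = ssgsea_score(np.exp(vals / 3.0), gene_set, cfg)
        assert s1 == pytest.approx(s2)

    def test_complement_set_negates_score_at_alpha_zero(self, rng):
        """Swapping set and complement swaps the two ECDFs up to the
        n/(n-k) vs n/k weighting; with alpha 0 the scores are opposite in
        sign after scaling by set sizes."""
        n, k = 12, 4
        vals = pd.Series(rng.permutation(np.arange(1.0, n + 1)),
                         index=[f"g{i}" for i in range(n)])
        gene_set = set(vals.index[:k])
        complement = set(vals.index[k:])
        cfg = SsgseaConfig(alpha=0.0)
        s_in = ssgsea_score(vals, gene_set, cfg)
        s_out = ssgsea_score(vals, complement, cfg)
        assert s_in * k == pytest.approx(-s_out * (n - k))

    def test_improper_sets_rejected(self):
        vals = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            ssgsea_score(vals, {"a", "b"})
        with pytest.raises(ValueError):
            ssgsea_score(vals, set())

    def test_planted_up_set_scores_higher(self, rng):
        """A gene set up-regulated in one group scores higher there
        (rank-sum p < 0.01 at 30 vs 30 samples)."""
        from crosstype.cross_species import wilcoxon_rank_sum
        n_genes, n_per = 300, 30
        base = rng.normal(5, 1, (n_genes, 2 * n_per))
        base[:20, :n_per] += 1.5
        df = pd.DataFrame(base, index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"s{i}" for i in range(2 * n_per)])
        scores = ssgsea_matrix(df, {"planted": [f"g{i}" for i in range(20)]})
        up = scores.iloc[:n_per, 0].to_numpy()
        ctrl = scores.iloc[n_per:, 0].to_numpy()
        assert up.mean() > ctrl.mean()
        _, p = wilcoxon_rank_sum(up, ctrl)
        assert p < 0.01


class TestCorrelationScreen:
    def test_exact_copy_is_positive_hit(self, rng):
        n = 50
        target = rng.uniform(2, 50, n)
        df = pd.DataFrame(rng.uniform(2, 50, (30, n)),
                          index=[f"g{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(n)])
        df.loc["copy"] = target
        df.loc["TARGET"] = target
        hits = correlation_screen(df, "TARGET")
        assert hits.loc["copy", "direction"] == "positive"
        assert hits.loc["copy", "pearson_r"] == pytest.approx(1.0)

    def test_null_hit_rate_below_one_percent(self, rng):
        n = 50
        df = pd.DataFrame(rng.uniform(2, 50, (2000, n)),
                          index=[f"g{i}" for i in range(2000)])
        df.loc["TARGET"] = rng.uniform(2, 50, n)
        hits = correlation_screen(df, "TARGET")
        assert len(hits) < 0.01 * 2000

    def test_unexpressed_target_skipped_with_warning(self, rng):
        df = pd.DataFrame(rng.uniform(2, 50, (10, 20)),
                          index=[f"g{i}" for i in range(10)])
        df.loc["TARGET"] = 0.01
        with pytest.warns(UserWarning, match="skipped"):
            hits = correlation_screen(df, "TARGET")
        assert hits.empty

    def test_too_few_samples_errors(self, rng):
        df = pd.DataFrame(rng.uniform(2, 50, (5, 4)), index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError):
            correlation_screen(df, "g0")


class TestSubgroupCrosstab:
    # printed PAM50-by-receptor-subgroup counts of the 143-tumor cohort
    TABLE = pd.DataFrame(
        {
            "ER-PR-": [17, 0, 2, 1, 0],
            "ER-PR+": [18, 0, 1, 3, 1],
            "ER+PR+": [6, 4, 6, 2, 2],
            "ER+PR-": [3, 2, 1, 0, 0],
            "cNBLMT": [5, 55, 8, 2, 4],
        },
        index=["Basal", "LumA", "LumB", "Her2", "Normal"],
    )

    def _labels_from_table(self):
        pam, grp = [], []
        for subtype in self.TABLE.index:
            for col in self.TABLE.columns:
                n = self.TABLE.loc[subtype, col]
                pam.extend([subtype] * n)
                grp.extend([col] * n)
        idx = [f"t{i}" for i in range(len(pam))]
        return pd.Series(pam, index=idx), pd.Series(grp, index=idx)

    def test_printed_cohort_shares(self):
        pam, grp = self._labels_from_table()
        out = subgroup_crosstab(pam, grp)
        assert out["n"] == 143
        assert out["col_totals"]["ER-PR+"] == 23
        assert out["col_pct"].loc["Basal", "ER-PR+"] == 78
        assert out["col_pct"].loc["Basal", "ER-PR-"] == 85
        assert out["col_pct"].loc["Basal", "ER+PR+"] == 30
        assert out["col_pct"].loc["Basal", "cNBLMT"] == 7

    def test_single_sample(self):
        out = subgroup_crosstab(pd.Series({"s": "A"}), pd.Series({"s": "x"}))
        assert out["counts"].loc["A", "x"] == 1
        assert out["col_pct"].loc["A", "x"] == 100

    def test_counts_sum_and_column_percentages(self, rng):
        a = pd.Series(rng.choice(list("AB"), 40))
        b = pd.Series(rng.choice(list("xyz"), 40))
        out = subgroup_crosstab(a, b)
        assert out["counts"].to_numpy().sum() == 40
        col_sums = out["col_pct"].sum(axis=0)
        assert ((col_sums - 100).abs() <= 1).all()   # integer rounding

    def test_mismatched_universe_errors(self):
        a = pd.Series({"s1": "A"})
        b = pd.Series({"s2": "B"})
        with pytest.raises(ValueError):
            subgroup_crosstab(a, b)
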