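import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.cluster import hierarchy

import crosstype as ct
from crosstype.cross_species import (
    SamplingScheme,
    cocluster_once,
    dendrogram_separation_cut,
    fisher_exact_2x2,
    homology_experiment,
    mahalanobis_center_distance,
    match_subtypes,
    mds_embed,
    sample_reference,
    wilcoxon_rank_sum,
)
from crosstype.pam50 import GenePanel


def _human_labels(sizes):
    idx, lab = [], []
    for st, n in sizes.items():
        for i in range(n):
            idx.append(f"{st}_{i}")
            lab.append(st)
    return pd.Series(lab, index=idx)


class TestSampleReference:
    SIZES = {"LumA": 100, "LumB": 80, "Basal": 90, "Her2": 70, "Normal": 27}

    def test_reference_size_267(self):
        labels = _human_labels(self.SIZES)
        ids = sample_reference(labels, SamplingScheme(seed=1), 0)
        assert len(ids) == 4 * 60 + 27
        drawn = labels.reindex(ids).value_counts()
        assert drawn["Normal"] == 27
        assert all(drawn[st] == 60 for st in ("LumA", "LumB", "Basal", "Her2"))

    def test_exhaustive_draw_no_duplicates(self):
        labels = _human_labels({"LumA": 60, "LumB": 80, "Basal": 90, "Her2": 70, "Normal": 5})
        ids = sample_reference(labels, SamplingScheme(seed=0), 3)
        luma = [s for s in ids if s.startswith("LumA")]
        assert sorted(luma) == sorted(labels.index[labels == "LumA"])
        assert len(set(ids)) == len(ids)

    def test_deterministic_per_repeat(self):
        labels = _human_labels(self.SIZES)
        s = SamplingScheme(seed=9)
        assert sample_reference(labels, s, 5) == sample_reference(labels, s, 5)
        assert sample_reference(labels, s, 5) != sample_reference(labels, s, 6)

    def test_small_subtype_errors(self):
        labels = _human_labels({"LumA": 10, "LumB": 80, "Basal": 90, "Her2": 70, "Normal": 5})
        with pytest.raises(ValueError, match="LumA"):
            sample_reference(labels, SamplingScheme(seed=0), 0)


class TestSeparationCut:
    def test_clean_split_k2(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (5, 3)), rng.normal(10, 0.1, (5, 3))])
        Z = hierarchy.linkage(pts, method="average")
        ids = [f"x{i}" for i in range(10)]
        k, clusters, S = dendrogram_separation_cut(Z, ids, ids[:5], ids[5:])
        assert (k, S) == (2, 1.0)
        assert clusters[ids[:5]].nunique() == 1
        assert clusters[ids[5:]].nunique() == 1

    def test_hand_built_four_leaf_tree(self):
        """Merge order a1+b1, then +a2, then +b2.  By hand: at k=2 the
        partition is {a1,b1,a2} | {b2}, so S(2) = (1 A-leaf in no-B
        clusters? no; b2 is the only pure leaf) = (0 + 1)/4 = 0.25; k=3 gives
        {a1,b1} | {a2} | {b2} with S = 2/4; only singletons (k=4) fully
        separate a1 from b1, giving S = 1."""
        Z = np.array([[0.0, 1.0, 1.0, 2],    # a1+b1
                      [4.0, 2.0, 2.0, 3],    # +a2
                      [5.0, 3.0, 4.0, 4]])   # +b2
        ids = ["a1", "b1", "a2", "b2"]
        k, _, S = dendrogram_separation_cut(Z, ids, ["a1", "a2"], ["b1", "b2"])
        assert (k, S) == (4, 1.0)
        # hand-checked intermediate score via a k_max-limited call
        k2, _, S2 = dendrogram_separation_cut(Z, ids, ["a1", "a2"], ["b1", "b2"], k_max=2)
        assert (k2, S2) == (2, 0.25)
        k3, _, S3 = dendrogram_separation_cut(Z, ids, ["a1", "a2"], ["b1", "b2"], k_max=3)
        assert (k3, S3) == (3, 0.5)

    def test_separation_monotone_on_random_trees(self, rng):
        from crosstype.cross_species import _nested_cuts
        for _ in range(5):
            pts = rng.normal(size=(12, 4))
            Z = hierarchy.linkage(pts, method="average")
            ids = list(range(12))
            isA = np.isin(ids, ids[:4])
            isB = np.isin(ids, ids[4:8])
            cuts = _nested_cuts(Z, 12)
            prev = -1.0
            for k in range(2, 13):
                lab = cuts[12 - k]
                assert len(np.unique(lab)) == k   # exact cluster count per cut
                nA = np.bincount(lab[isA], minlength=int(lab.max()) + 1)
                nB = np.bincount(lab[isB], minlength=int(lab.max()) + 1)
                S = (nA[nB == 0].sum() + nB[nA == 0].sum()) / 8
                assert S >= prev - 1e-12
                prev = S
            assert prev == 1.0   # disjoint groups fully separate at singletons


class TestMatchSubtypes:
    def test_constructed_majority_case(self):
        clusters = pd.Series(
            [0] * 55 + [1] * 5 + [0] * 60 + [1] * 9,
            index=[f"h{i}" for i in range(60)] + [f"c{i}" for i in range(69)],
        )
        human = pd.Series(["hBLBC"] * 60, index=[f"h{i}" for i in range(60)])
        canine = pd.Series(["cBLMT"] * 69, index=[f"c{i}" for i in range(69)])
        assert match_subtypes(clusters, canine, human) == [("cBLMT", "hBLBC")]

    def test_even_split_is_no_majority(self):
        clusters = pd.Series([0] * 30 + [1] * 30 + [0] * 40,
                             index=[f"h{i}" for i in range(60)] + [f"c{i}" for i in range(40)])
        human = pd.Series(["hBLBC"] * 60, index=[f"h{i}" for i in range(60)])
        canine = pd.Series(["cX"] * 40, index=[f"c{i}" for i in range(40)])
        assert match_subtypes(clusters, canine, human) == []

    def test_private_cluster_matches_nothing(self):
        clusters = pd.Series([0] * 10 + [1] * 10,
                             index=[f"c{i}" for i in range(10)] + [f"h{i}" for i in range(10)])
        canine = pd.Series(["cN"] * 10, index=[f"c{i}" for i in range(10)])
        human = pd.Series(["hL"] * 10, index=[f"h{i}" for i in range(10)])
        assert match_subtypes(clusters, canine, human) == []


class TestCoclusterOnce:
    def _cohorts(self):
        cfg = ct.homology_study_config(seed=31)
        expr, meta, truth = ct.simulate_cohort(cfg)
        log2 = ct.fpkm_to_tpm(ct.counts_to_fpkm(expr, truth.gene_lengths)).log2p1()
        canine = meta.table.index[meta.table.species == "canine"]
        human = meta.table.index[meta.table.species == "human"]
        return log2, canine, human, truth

    def test_planted_homology_and_non_homology(self, homology_cohort):
        log2, meta, truth = homology_cohort
        canine = meta.table.index[meta.table.species == "canine"]
        human = meta.table.index[meta.table.species == "human"]
        labels = truth.subtype_label
        ids = sample_reference(labels.loc[human], SamplingScheme(seed=4), 0)
        rec = cocluster_once(
            log2.subset_samples(canine), log2.subset_samples(ids),
            GenePanel(tuple(truth.panel_genes)),
            labels.loc[canine], labels.reindex(ids))
        assert ("cBLMT", "Basal") in rec["matches"]
        assert not any(c == "cNBLMT" for c, _ in rec["matches"])

    def test_duplicate_reference_self_homology(self, homology_cohort):
        log2, meta, truth = homology_cohort
        human = meta.table.index[meta.table.species == "human"]
        labels = truth.subtype_label.loc[human]
        dup = log2.subset_samples(human)
        dup_renamed = ct.ExprMatrix(
            dup.data.rename(columns={s: f"dup_{s}" for s in dup.samples}), "log2tpm")
        dup_labels = pd.Series(labels.to_numpy(), index=[f"dup_{s}" for s in labels.index])
        rec = cocluster_once(dup_renamed, dup, GenePanel(tuple(truth.panel_genes)),
                             dup_labels, labels)
        for st in ("Basal", "LumA", "LumB", "Her2", "Normal"):
            assert (st, st) in rec["matches"]

    def test_no_shared_genes_errors(self, homology_cohort):
        log2, meta, truth = homology_cohort
        canine = meta.table.index[meta.table.species == "canine"]
        human = meta.table.index[meta.table.species == "human"]
        with pytest.raises(ValueError, match="shared"):
            cocluster_once(log2.subset_samples(canine), log2.subset_samples(human),
                           GenePanel(("absent1", "absent2", "absent3")),
                           truth.subtype_label.loc[canine], truth.subtype_label.loc[human])


class TestHomologyExperiment:
    def test_single_repeat_aggregate_equals_repeat(self, homology_cohort):
        log2, meta, truth = homology_cohort
        canine = meta.table.index[meta.table.species == "canine"]
        human = meta.table.index[meta.table.species == "human"]
        res = homology_experiment(
            log2.subset_samples(canine), truth.subtype_label.loc[canine],
            log2.subset_samples(human), truth.subtype_label.loc[human],
            GenePanel(tuple(truth.panel_genes)),
            SamplingScheme(n_repeats=1, seed=2),
            pair1=("cBLMT", "Basal"), pair2=("cNBLMT", "LumA"))
        assert len(res.per_repeat) == 1
        assert res.match_counts.sum() == len(res.per_repeat[0]["matches"])
        assert res.fisher_table[0].sum() == 1 and res.fisher_table[1].sum() == 1


class TestMDS:
    def test_collinear_three_points(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        coords = mds_embed(D, 1)
        x = np.sort(coords[:, 0])
        gaps = np.diff(x)
        np.testing.assert_allclose(gaps, [1.0, 1.0], atol=1e-8)

    def test_round_trip_from_plane(self, rng):
        pts = rng.normal(size=(10, 2))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(pts))
        coords = mds_embed(D, 2)
        D2 = squareform(pdist(coords))
        np.testing.assert_allclose(D, D2, atol=1e-8)

    def test_identical_points_zero_coords(self):
        with pytest.warns(UserWarning, match="padding"):
            coords = mds_embed(np.zeros((4, 4)), 2)
        np.testing.assert_allclose(coords, 0.0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            mds_embed(np.array([[0.0, 1.0], [2.0, 0.0]]), 1)


class TestMahalanobis:
    def test_identical_means_zero(self, rng):
        A = rng.normal(size=(20, 2))
        B = A + 0.0
        assert mahalanobis_center_distance(A, B) == pytest.approx(0.0, abs=1e-6)

    def test_identity_covariance_equals_euclidean(self, rng):
        # whitened groups: large n so pooled covariance ~ identity
        rng = np.random.default_rng(12)
        A = rng.normal(0, 1, (4000, 2))
        B = rng.normal(0, 1, (4000, 2)) + np.array([3.0, 4.0])
        d = mahalanobis_center_distance(A, B)
        euclid = np.linalg.norm(A.mean(0) - B.mean(0))
        assert d == pytest.approx(euclid, rel=0.05)

    def test_matches_direct_inversion_oracle(self, rng):
        A = rng.normal(size=(15, 2)) @ np.array([[2.0, 0.3], [0.1, 0.5]])
        B = rng.normal(size=(12, 2)) + 1.0
        Sa, Sb = np.cov(A, rowvar=False), np.cov(B, rowvar=False)
        pooled = (14 * Sa + 11 * Sb) / 25 + 1e-8 * np.eye(2)
        diff = A.mean(0) - B.mean(0)
        expected = float(np.sqrt(diff @ np.linalg.inv(pooled) @ diff))
        assert mahalanobis_center_distance(A, B) == pytest.approx(expected, rel=1e-9)

    def test_too_few_points_errors(self, rng):
        with pytest.raises(ValueError):
            mahalanobis_center_distance(rng.normal(size=(2, 2)), rng.normal(size=(5, 2)))


def _fisher_enumeration_oracle(table):
    """Exact two-sided Fisher p with rational arithmetic."""
    a, b, c, d = (int(x) for x in np.asarray(table).ravel())
    n, r1, c1 = a + b + c + d, a + b, a + c

    def prob(x):
        return Fraction(comb(r1, x) * comb(n - r1, c1 - x), comb(n, c1))

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs))


class TestFisherExact:
    def test_balanced_table_p_one(self):
        _, p = fisher_exact_2x2([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)

    def test_diagonal_table(self):
        _, p = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_matches_enumeration_and_scipy(self, rng):
        for _ in range(50):
            t = rng.integers(0, 25, (2, 2))
            _, p = fisher_exact_2x2(t)
            assert p == pytest.approx(_fisher_enumeration_oracle(t), abs=1e-12)
            assert p == pytest.approx(sps.fisher_exact(t)[1], abs=1e-9)

    def test_transpose_invariance(self, rng):
        for _ in range(20):
            t = rng.integers(0, 30, (2, 2))
            assert fisher_exact_2x2(t)[1] == pytest.approx(fisher_exact_2x2(t.T)[1], abs=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_exact(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments as extreme

    def test_exact_matches_enumeration(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        _, p = wilcoxon_rank_sum(x, y)
        # enumerate all C(10,5) group assignments of the pooled values
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        u_obs = ranks[:5].sum() - 5 * 6 / 2
        stats = []
        for combo in itertools.combinations(range(10), 5):
            u = ranks[list(combo)].sum() - 5 * 6 / 2
            stats.append(u)
        stats = np.asarray(stats)
        dev = np.abs(stats - 12.5)      # center of U under H0 = nm/2
        p_exact = float((dev >= np.abs(u_obs - 12.5) - 1e-9).mean())
        assert p == pytest.approx(p_exact, abs=1e-12)

    def test_asymptotic_close_to_exact_at_n10(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10) + 0.5
        _, p_asym = wilcoxon_rank_sum(x, y)   # n+m=20 -> asymptotic branch
        p_exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert abs(p_asym - p_exact) < 0.02

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])
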