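"""End-to-end study drivers at desk scale.

Each function runs one complete analysis on synthetic cohorts (or, for the
receptor-subgroup worked example, on the printed cohort table) and returns
the headline quantities.  The analysis scripts, the test suite and the
acceptance script all call these, so the numbers they report are always
recomputed from scratch by the package itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import train_test_split

from . import (
    ExprMatrix,
    counts_to_fpkm,
    fpkm_to_tpm,
    homology_study_config,
    recovery_study_config,
    simulate_cohort,
)
from .cross_species import SamplingScheme, fisher_exact_2x2, homology_experiment
from .expression_stats import nb_wald_de, subgroup_crosstab
from .feature_selection import BorutaConfig, stable_feature_genes
from .pam50 import GenePanel, build_centroids, classify
from .preprocess import top_variable_genes
from .subtype_discovery import consensus_subtypes

# Published PAM50-by-receptor-subgroup counts of a 143-tumor canine cohort
# (69 basal-like tumors split into four ER/PR subgroups, 74 non-basal-like
# tumors pooled), used as the worked crosstab example.
TABLE1_COUNTS = pd.DataFrame(
    {
        "ER-PR-": [17, 0, 2, 1, 0],
        "ER-PR+": [18, 0, 1, 3, 1],
        "ER+PR+": [6, 4, 6, 2, 2],
        "ER+PR-": [3, 2, 1, 0, 0],
        "cNBLMT": [5, 55, 8, 2, 4],
    },
    index=["Basal", "LumA", "LumB", "Her2", "Normal"],
)

# Published per-pair co-clustering tallies over 100 reference resamplings:
# basal pair clustered together in 66, the luminal/non-basal pair in 13.
FIG2C_TABLE = np.array([[66, 34], [13, 87]])


def _expand_counts(table: pd.DataFrame):
    rows, cols = [], []
    for r in table.index:
        for c in table.columns:
            n = int(table.loc[r, c])
            rows.extend([r] * n)
            cols.extend([c] * n)
    idx = [f"t{i}" for i in range(len(rows))]
    return pd.Series(rows, index=idx), pd.Series(cols, index=idx)


def table1_shares(table: pd.DataFrame | None = None) -> dict:
    """Crosstab shares of the printed PAM50-by-subgroup cohort table."""
    table = TABLE1_COUNTS if table is None else table
    pam, grp = _expand_counts(table)
    out = subgroup_crosstab(pam, grp)
    pct = out["col_pct"]
    blmt_cols = ["ER-PR-", "ER-PR+", "ER+PR+", "ER+PR-"]
    n_blmt = int(out["col_totals"][blmt_cols].sum())
    return {
        "n": out["n"],
        "basal_share_er_neg_pr_pos_pct": int(pct.loc["Basal", "ER-PR+"]),
        "basal_share_er_neg_pr_neg_pct": int(pct.loc["Basal", "ER-PR-"]),
        "basal_share_er_pos_pr_pos_pct": int(pct.loc["Basal", "ER+PR+"]),
        "basal_share_nonbasal_subtype_pct": int(pct.loc["Basal", "cNBLMT"]),
        "er_neg_pr_pos_share_of_blmt_pct": int(round(
            100 * out["col_totals"]["ER-PR+"] / n_blmt)),
        "er_pos_pr_neg_share_of_blmt_pct": int(round(
            100 * out["col_totals"]["ER+PR-"] / n_blmt)),
    }


def _log2tpm(expr, lengths):
    return fpkm_to_tpm(counts_to_fpkm(expr, lengths)).log2p1()


def subtype_recovery_study(n_seeds: int = 20, base_seed: int = 0) -> pd.DataFrame:
    """Consensus-NMF subtype recovery on planted 143-sample cohorts.

    One row per seed: adjusted Rand index of the consensus labels against
    the planted subtypes (on consistently assigned samples) and the
    fraction of consistent samples.
    """
    rows = []
    for i in range(n_seeds):
        seed = (base_seed + i) % (2**31)
        cfg = recovery_study_config(seed=seed)
        expr, _, truth = simulate_cohort(cfg)
        log2 = _log2tpm(expr, truth.gene_lengths)
        subsets = {
            "all": list(log2.genes),
            "top400": top_variable_genes(log2, 400),
            "top200": top_variable_genes(log2, 200),
        }
        res = consensus_subtypes(log2, gene_subsets=subsets, rank=2, n_runs=30, seed=seed)
        keep = res.consistent
        ari = adjusted_rand_score(truth.subtype_label[keep],
                                  res.consensus_label[keep].astype(int))
        rows.append({"seed": seed, "ari": ari, "consistent_frac": float(keep.mean())})
    return pd.DataFrame(rows)


def homology_study(seed: int = 0, n_repeats: int = 100) -> dict:
    """Cross-species co-clustering on a cohort with one planted homologous
    pair (cBLMT ~ human basal-like) and one species-private canine subtype."""
    cfg = homology_study_config(seed=seed)
    expr, meta, truth = simulate_cohort(cfg)
    log2 = _log2tpm(expr, truth.gene_lengths)
    canine = meta.table.index[meta.table.species == "canine"]
    human = meta.table.index[meta.table.species == "human"]
    labels = truth.subtype_label
    panel = GenePanel(tuple(truth.panel_genes), "synthetic panel")
    scheme = SamplingScheme(n_per_subtype=60, n_repeats=n_repeats, seed=seed)
    res = homology_experiment(
        log2.subset_samples(canine), labels.loc[canine],
        log2.subset_samples(human), labels.loc[human],
        panel, scheme, pair1=("cBLMT", "Basal"), pair2=("cNBLMT", "LumA"))

    dd = res.distance_distributions
    key = "c:cBLMT|h:Basal"
    named = [c for c in dd.columns
             if c.startswith("c:") and "|h:" in c or c == "h:Basal|h:LumA"]
    others = [c for c in named if c != key]
    smallest = float((dd[key] < dd[others].min(axis=1)).mean()) if key in dd else 0.0
    counts = {f"{c}~{h}": int(n) for (c, h), n in res.match_counts.items()}
    return {
        "n_repeats": n_repeats,
        "homologous_matches": counts.get("cBLMT~Basal", 0),
        "nonhomologous_matches": counts.get("cNBLMT~LumA", 0),
        "match_counts": counts,
        "fisher_table": res.fisher_table.tolist(),
        "fisher_p": float(res.fisher_p),
        "homologous_distance_smallest_frac": smallest,
        "mean_distances": dd.mean().to_dict(),
        "wilcoxon_p": {f"{a} vs {b}": float(p) for (a, b), p in res.wilcoxon_p.items()},
    }


def fisher_oracle_study(seed: int = 0, n_tables: int = 1000) -> dict:
    """Agreement of the Fisher test with full hypergeometric enumeration."""
    from fractions import Fraction
    from math import comb

    def oracle(a, b, c, d):
        n, r1, c1 = a + b + c + d, a + b, a + c
        if min(r1, c + d, c1, b + d) == 0:
            return 1.0
        probs = {x: Fraction(comb(r1, x) * comb(n - r1, c1 - x), comb(n, c1))
                 for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)}
        p_obs = probs[a]
        return float(sum(p for p in probs.values() if p <= p_obs))

    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_tables):
        a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
        _, p = fisher_exact_2x2([[a, b], [c, d]])
        max_err = max(max_err, abs(p - oracle(a, b, c, d)))
    _, p_fig2c = fisher_exact_2x2(FIG2C_TABLE)
    return {"n_tables": n_tables, "max_abs_error": max_err,
            "fig2c_counts_p": float(p_fig2c)}


def de_calibration_study(seed: int = 0, n_genes: int = 2000, n_per_group: int = 10) -> dict:
    """Type-I error under the null and power on planted 4-fold genes."""
    rng = np.random.default_rng(seed)

    def draw(mu):
        n = 1 / 0.15
        return rng.negative_binomial(n, n / (n + mu[:, None]), (mu.size, n_per_group))

    mu = np.exp(rng.normal(3.0, 1.2, n_genes))
    null_counts = pd.DataFrame(
        np.hstack([draw(mu), draw(mu)]),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(2 * n_per_group)])
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group,
                       index=null_counts.columns)
    res_null = nb_wald_de(null_counts, groups)

    n_planted = 200
    lfc = np.zeros(n_genes)
    lfc[:n_planted] = 2.0
    planted_counts = pd.DataFrame(
        np.hstack([draw(mu), draw(mu * 2.0 ** lfc)]),
        index=null_counts.index, columns=null_counts.columns)
    res_planted = nb_wald_de(planted_counts, groups)
    return {
        "null_type1_at_p05": float((res_null.p < 0.05).mean()),
        "null_bh_significant": int(res_null.significant.sum()),
        "power_fourfold": float(res_planted.significant.iloc[:n_planted].mean()),
        "n_genes": n_genes,
        "n_per_group": n_per_group,
    }


def boruta_recovery_study(seed: int = 0, n_genes: int = 2000, n_planted: int = 30,
                          n_per_group: int = 60) -> dict:
    """Stable feature-gene recovery of planted discriminative genes."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(3.0, 1.0, n_genes))
    lfc = np.zeros(n_genes)
    lfc[: n_planted // 2] = 2.0
    lfc[n_planted // 2: n_planted] = -2.0

    def draw(m):
        n = 1 / 0.15
        return rng.negative_binomial(n, n / (n + m[:, None]), (m.size, n_per_group))

    counts = pd.DataFrame(
        np.hstack([draw(mu), draw(np.clip(mu * 2.0 ** lfc, 1e-6, None))]),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(2 * n_per_group)])
    labels = pd.Series(["other"] * n_per_group + ["target"] * n_per_group,
                       index=counts.columns)
    cfg = BorutaConfig(n_trees=300, max_rounds=40, n_outer_repeats=10,
                       freq_cutoff=10, seed=seed)
    fs = stable_feature_genes(counts, labels, "target", config=cfg)
    planted = set(counts.index[:n_planted])
    selected = set(fs.genes)
    return {
        "n_planted": n_planted,
        "recovered": len(selected & planted),
        "false_positives": len(selected - planted),
        "heldout_accuracy": fs.heldout_accuracy,
    }


def classifier_study(seed: int = 0) -> dict:
    """Held-out nearest-centroid accuracy on a five-subtype reference, plus
    exact invariance of the calls under a per-sample monotone transform."""
    cfg = homology_study_config(seed=seed)
    expr, meta, truth = simulate_cohort(cfg)
    log2 = _log2tpm(expr, truth.gene_lengths)
    human = meta.table.index[meta.table.species == "human"]
    h = log2.subset_samples(human)
    labels = truth.subtype_label.loc[human]
    idx = np.arange(h.shape[1])
    tr, te = train_test_split(idx, train_size=0.7, stratify=labels,
                              random_state=seed % (2**31))
    panel = GenePanel(tuple(truth.panel_genes), "synthetic panel")
    model = build_centroids(h.subset_samples(h.samples[tr]), labels.iloc[tr], panel)
    test_expr = h.subset_samples(h.samples[te])
    calls = classify(test_expr, model)
    acc = float((calls["label"].to_numpy() == labels.iloc[te].to_numpy()).mean())
    warped = ExprMatrix(np.exp(test_expr.data / 4.0), "log2tpm")
    invariant = bool((classify(warped, model)["label"] == calls["label"]).all())
    return {"heldout_accuracy": acc, "n_test": int(len(te)),
            "monotone_invariant": invariant}
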