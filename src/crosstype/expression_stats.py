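"""Downstream expression statistics.

Differential expression uses a negative-binomial Wald test: counts are
normalized with median-of-ratios size factors, per-gene dispersions are
method-of-moments estimates shrunk halfway toward a fitted mean-dispersion
trend, and the log2 fold change is tested with a standard error from the NB
GLM information.  Significance combines a fold-change cutoff with
Benjamini-Hochberg adjusted p-values.  ssGSEA scores are rank-weighted
running-sum differences between a gene set and its complement, computed
per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import ExprMatrix

__all__ = [
    "size_factors",
    "nb_wald_de",
    "bh_adjust",
    "SsgseaConfig",
    "ssgsea_score",
    "ssgsea_matrix",
    "correlation_screen",
    "subgroup_crosstab",
]


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors (relative to the geometric mean gene).

    Only genes with positive counts in every sample contribute; lacking any
    such gene the factors are undefined and an error is raised.
    """
    data = counts.data if isinstance(counts, ExprMatrix) else pd.DataFrame(counts)
    arr = data.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with positive counts in all samples; size factors undefined")
    logs = np.log(arr[allpos])
    log_geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(factors, index=data.columns, name="size_factor")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fit_dispersion_trend(mean_, disp_mom):
    """Fit a_0 + a_1/mean to positive method-of-moments dispersions."""
    ok = (disp_mom > 0) & (mean_ > 0)
    if ok.sum() < 10:
        return lambda m: np.full_like(m, max(float(np.median(disp_mom[ok])) if ok.any() else 0.1, 1e-8))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mean_[ok]])
    coef, *_ = np.linalg.lstsq(X, disp_mom[ok], rcond=None)
    a0, a1 = coef

    def trend(m):
        return np.clip(a0 + a1 / np.maximum(m, 1e-8), 1e-8, 10.0)

    return trend


def nb_wald_de(counts, groups, fold_cutoff: float = 2.0, alpha: float = 0.05) -> pd.DataFrame:
    """Two-group NB Wald differential-expression test.

    Parameters
    ----------
    counts:
        ExprMatrix of raw counts (or a DataFrame, genes x samples).
    groups:
        Per-sample labels with exactly two levels; the log2 fold change is
        level2 vs level1 in sorted label order.
    fold_cutoff, alpha:
        Significance requires |log2FC| >= log2(fold_cutoff) and BH-adjusted
        p <= alpha.

    Returns a DataFrame with base_mean, log2_fc, p, padj and significant.
    """
    data = counts.data if isinstance(counts, ExprMatrix) else pd.DataFrame(counts)
    groups = pd.Series(groups, index=data.columns) if not isinstance(groups, pd.Series) \
        else groups.reindex(data.columns)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"nb_wald_de requires exactly two groups, got {levels}")
    idx1 = groups == levels[0]
    idx2 = groups == levels[1]
    if idx1.sum() < 3 or idx2.sum() < 3:
        raise ValueError("each group needs at least 3 samples")

    sf = size_factors(data).to_numpy()
    arr = data.to_numpy(dtype=float)
    norm = arr / sf[None, :]
    n1, n2 = int(idx1.sum()), int(idx2.sum())
    m1 = norm[:, idx1.values].mean(axis=1)
    m2 = norm[:, idx2.values].mean(axis=1)
    base_mean = norm.mean(axis=1)

    # method-of-moments dispersion from within-group residuals, then 50/50
    # shrinkage toward an a0 + a1/mean trend
    v1 = norm[:, idx1.values].var(axis=1, ddof=1)
    v2 = norm[:, idx2.values].var(axis=1, ddof=1)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    pooled_mean = (n1 * m1 + n2 * m2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = (pooled_var - pooled_mean) / np.square(pooled_mean)
    disp_mom = np.where(np.isfinite(disp_mom), disp_mom, 0.0)
    trend = _fit_dispersion_trend(pooled_mean, np.clip(disp_mom, 0.0, 10.0))
    disp = 0.5 * np.clip(disp_mom, 1e-8, 10.0) + 0.5 * trend(pooled_mean)

    # Wald statistic on the log fold change; a half-count prior on each
    # group mean keeps zero-count genes finite
    pc1 = 0.5 / sf[idx1.values].sum()
    pc2 = 0.5 / sf[idx2.values].sum()
    lfc_ln = np.log(m2 + pc2) - np.log(m1 + pc1)
    s1 = sf[idx1.values]
    s2 = sf[idx2.values]
    # information for the log-mean in each group: sum_i mu_i / (1 + disp*mu_i)
    mu1 = np.maximum(m1, pc1)[:, None] * s1[None, :]
    mu2 = np.maximum(m2, pc2)[:, None] * s2[None, :]
    info1 = (mu1 / (1.0 + disp[:, None] * mu1)).sum(axis=1)
    info2 = (mu2 / (1.0 + disp[:, None] * mu2)).sum(axis=1)
    se_ln = np.sqrt(1.0 / info1 + 1.0 / info2)
    z = lfc_ln / se_ln
    p = 2.0 * sps.norm.sf(np.abs(z))
    # genes with equal normalized group means, and genes whose raw counts are
    # literally identical in every sample, are definitionally non-differential
    constant_raw = (arr == arr[:, :1]).all(axis=1)
    same = np.isclose(m1, m2) | constant_raw
    p = np.where(same, 1.0, p)
    log2_fc = np.where(same, 0.0, lfc_ln / np.log(2.0))
    padj = bh_adjust(p)
    significant = (np.abs(log2_fc) >= np.log2(fold_cutoff)) & (padj <= alpha)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "p": p,
            "padj": padj,
            "significant": significant,
        },
        index=data.index,
    )


@dataclass(frozen=True)
class SsgseaConfig:
    alpha: float = 0.75        # rank-weight exponent on |expression|
    normalize: bool = False    # divide scores by the global score range

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("ssGSEA weight exponent must be >= 0")


def ssgsea_score(expr_sample: pd.Series, gene_set, config: SsgseaConfig | None = None) -> float:
    """Single-sample gene-set enrichment score.

    Genes are ranked by expression descending (ties broken by gene id); the
    score is the summed difference between the |value|^alpha-weighted ECDF of
    set members and the uniform ECDF of non-members along the ranking.
    """
    config = config or SsgseaConfig()
    values = pd.Series(expr_sample)
    in_set = values.index.isin(set(gene_set))
    n_in = int(in_set.sum())
    if n_in == 0 or n_in == len(values):
        raise ValueError("gene set must be a proper nonempty subset of the measured genes")
    order = sorted(range(len(values)),
                   key=lambda i: (-values.iloc[i], values.index[i]))
    v = values.to_numpy(dtype=float)[order]
    member = in_set[order]
    w = np.abs(v) ** config.alpha
    w_in = np.where(member, w, 0.0)
    denom = w_in.sum()
    if denom <= 0:           # all set members at zero expression: uniform weights
        w_in = member.astype(float)
        denom = w_in.sum()
    ecdf_in = np.cumsum(w_in) / denom
    ecdf_out = np.cumsum(~member) / (len(values) - n_in)
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea_matrix(expr, gene_sets: dict, config: SsgseaConfig | None = None) -> pd.DataFrame:
    """ssGSEA scores for every sample x gene set; optional range normalization."""
    config = config or SsgseaConfig()
    data = expr.data if isinstance(expr, ExprMatrix) else pd.DataFrame(expr)
    out = pd.DataFrame(
        {name: [ssgsea_score(data[s], genes, config) for s in data.columns]
         for name, genes in gene_sets.items()},
        index=data.columns,
    )
    if config.normalize:
        span = out.to_numpy().max() - out.to_numpy().min()
        if span > 0:
            out = out / span
    return out


def correlation_screen(expr, target_gene: str, subtype_samples=None, r_cutoff: float = 0.3,
                       alpha: float = 0.05, min_fpkm: float = 1.0,
                       min_frac: float = 0.10) -> pd.DataFrame:
    """Dual Pearson/Spearman correlation screen against a target gene.

    Genes expressed above ``min_fpkm`` in at least ``min_frac`` of the
    subtype's samples are screened; a hit requires |R| > r_cutoff with the
    same sign for BOTH coefficients and BH-adjusted p < alpha in both
    families (each coefficient's p-values adjusted separately).
    """
    data = expr.data if isinstance(expr, ExprMatrix) else pd.DataFrame(expr)
    if subtype_samples is not None:
        data = data[list(subtype_samples)]
    if data.shape[1] < 5:
        raise ValueError("correlation screen needs at least 5 samples")
    if target_gene not in data.index:
        raise ValueError(f"target gene {target_gene!r} not in the matrix")
    expressed = (data > min_fpkm).mean(axis=1) >= min_frac
    if not expressed.loc[target_gene]:
        warnings.warn(
            f"target gene {target_gene} expressed above {min_fpkm} in fewer than "
            f"{min_frac:.0%} of samples; screen skipped", stacklevel=2)
        return pd.DataFrame(columns=["pearson_r", "pearson_p", "spearman_r", "spearman_p",
                                     "pearson_padj", "spearman_padj", "direction"])
    genes = [g for g in data.index[expressed] if g != target_gene]
    y = data.loc[target_gene].to_numpy(dtype=float)
    X = data.loc[genes].to_numpy(dtype=float)

    pr, pp, sr, sp_ = [], [], [], []
    for row in X:
        r, p = sps.pearsonr(row, y)
        pr.append(r)
        pp.append(p)
        r, p = sps.spearmanr(row, y)
        sr.append(r)
        sp_.append(p)
    res = pd.DataFrame(
        {"pearson_r": pr, "pearson_p": pp, "spearman_r": sr, "spearman_p": sp_},
        index=genes,
    ).replace({np.nan: 0.0})
    res["pearson_p"] = res["pearson_p"].clip(0, 1)
    res["spearman_p"] = res["spearman_p"].clip(0, 1)
    res["pearson_padj"] = bh_adjust(res["pearson_p"].to_numpy())
    res["spearman_padj"] = bh_adjust(res["spearman_p"].to_numpy())
    pos = (res.pearson_r > r_cutoff) & (res.spearman_r > r_cutoff)
    neg = (res.pearson_r < -r_cutoff) & (res.spearman_r < -r_cutoff)
    sig = (res.pearson_padj < alpha) & (res.spearman_padj < alpha)
    res["direction"] = np.where(pos & sig, "positive", np.where(neg & sig, "negative", "none"))
    return res[res.direction != "none"].copy()


def subgroup_crosstab(labels_a, labels_b) -> dict:
    """Contingency table of two per-sample categorical labelings.

    Returns counts, column percentages (rounded to integer), and marginals.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if not a.index.equals(b.index):
        if len(a) != len(b) or set(a.index) != set(b.index):
            raise ValueError("label vectors cover different sample universes")
        b = b.reindex(a.index)
    counts = pd.crosstab(a, b)
    col_pct = (counts / counts.sum(axis=0) * 100).round().astype(int)
    return {
        "counts": counts,
        "col_pct": col_pct,
        "row_totals": counts.sum(axis=1),
        "col_totals": counts.sum(axis=0),
        "n": int(counts.to_numpy().sum()),
    }
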