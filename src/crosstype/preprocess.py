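"""Expression filtering, scaling, batch correction and receptor-status calls.

Receptor status follows the transcript-abundance rule used for
immunohistochemistry-free cohorts: ER/PR positive when the marker gene
(ESR1/PGR) exceeds FPKM 1, HER2 enriched when ERBB2 exceeds FPKM 35.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExprMatrix

__all__ = [
    "ReceptorThresholds",
    "filter_expressed_genes",
    "top_variable_genes",
    "row_zscale",
    "combat_correct",
    "call_receptor_status",
]

SUBGROUPS = ("ER-PR-", "ER-PR+", "ER+PR+", "ER+PR-")


@dataclass(frozen=True)
class ReceptorThresholds:
    er_pr_fpkm: float = 1.0
    her2_fpkm: float = 35.0

    def __post_init__(self) -> None:
        if self.er_pr_fpkm <= 0 or self.her2_fpkm <= 0:
            raise ValueError("receptor thresholds must be positive")


def filter_expressed_genes(expr: ExprMatrix, named_genes=None, min_fpkm: float = 1.0,
                           min_samples: int = 1) -> list[str]:
    """Genes (within ``named_genes``) with FPKM >= min_fpkm in >= min_samples samples."""
    if expr.unit != "fpkm":
        raise ValueError(f"filter_expressed_genes expects fpkm, got {expr.unit!r}")
    if named_genes is None:
        named_genes = list(expr.genes)
    else:
        unknown = set(named_genes) - set(expr.genes)
        if unknown:
            raise ValueError(f"named genes absent from matrix: {sorted(unknown)[:5]}")
    sub = expr.data.loc[list(named_genes)]
    keep = (sub >= min_fpkm).sum(axis=1) >= min_samples
    out = list(sub.index[keep])
    if not out:
        warnings.warn("no genes pass the expression filter", stacklevel=2)
    return out


def top_variable_genes(expr: ExprMatrix, k) -> list[str]:
    """Top-k (count or fraction) genes by variance, ties broken by gene id."""
    n = expr.shape[0]
    if isinstance(k, float) and 0 < k <= 1:
        k = int(round(k * n))
    k = int(k)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available genes")
    var = expr.data.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:k]


def row_zscale(expr) -> pd.DataFrame:
    """Center and scale each gene row to mean 0, sd 1 (sample sd, n-1).

    Constant rows map to all-zero rather than NaN so that downstream
    distance computations stay finite.
    """
    data = expr.data if isinstance(expr, ExprMatrix) else pd.DataFrame(expr)
    mu = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    out = data.sub(mu, axis=0)
    nz = sd > 0
    out.loc[nz] = out.loc[nz].div(sd[nz], axis=0)
    out.loc[~nz] = 0.0
    return out


def combat_correct(expr, batch) -> pd.DataFrame:
    """Parametric empirical-Bayes location-scale batch correction.

    Standardizes each gene, estimates per-batch location/scale parameters,
    shrinks them toward batch-level priors and adjusts — the classical
    ComBat model, applied on log2(TPM+1) values.  A single batch is a no-op;
    a batch with fewer than two samples is an error.
    """
    data = expr.data if isinstance(expr, ExprMatrix) else pd.DataFrame(expr)
    batch = pd.Series(batch, index=data.columns) if not isinstance(batch, pd.Series) else batch
    batch = batch.reindex(data.columns)
    if batch.isna().any():
        raise ValueError("batch labels missing for some samples")
    sizes = batch.value_counts()
    if len(sizes) == 1:
        return data.copy()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"batch(es) with a single sample: {list(small.index)}")

    import anndata
    import scanpy as sc

    # drop zero-variance genes (ComBat's standardization is undefined there)
    sd = data.std(axis=1, ddof=1)
    keep = sd > 0
    adata = anndata.AnnData(
        X=data.loc[keep].to_numpy().T.astype(np.float64),
        obs=pd.DataFrame({"batch": batch.astype(str).values},
                         index=data.columns.astype(str)),
        var=pd.DataFrame(index=data.index[keep].astype(str)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.combat(adata, key="batch")
    out = data.copy()
    out.loc[keep] = adata.X.T
    return out


def call_receptor_status(expr: ExprMatrix, marker_genes: dict,
                         thresholds: ReceptorThresholds | None = None) -> pd.DataFrame:
    """Threshold ER/PR/HER2 marker expression into receptor status calls.

    Returns a DataFrame indexed by sample with columns ``ER`` (neg/pos),
    ``PR`` (neg/pos), ``HER2`` (not_enriched/enriched) and ``subgroup``.
    Positivity is strict: FPKM equal to the threshold is negative.
    """
    if expr.unit != "fpkm":
        raise ValueError(f"call_receptor_status expects fpkm, got {expr.unit!r}")
    thresholds = thresholds or ReceptorThresholds()
    for key in ("ER", "PR", "HER2"):
        g = marker_genes.get(key)
        if g is None or g not in expr.genes:
            raise ValueError(f"marker gene for {key} ({g!r}) not in the matrix")
    er = expr.data.loc[marker_genes["ER"]] > thresholds.er_pr_fpkm
    pr = expr.data.loc[marker_genes["PR"]] > thresholds.er_pr_fpkm
    her2 = expr.data.loc[marker_genes["HER2"]] > thresholds.her2_fpkm
    subgroup = [
        f"ER{'+' if e else '-'}PR{'+' if p else '-'}" for e, p in zip(er, pr)
    ]
    return pd.DataFrame(
        {
            "ER": np.where(er, "pos", "neg"),
            "PR": np.where(pr, "pos", "neg"),
            "HER2": np.where(her2, "enriched", "not_enriched"),
            "subgroup": subgroup,
        },
        index=expr.samples,
    )
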