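"""Panel-based nearest-centroid subtype classification.

The classifier is trained from a labeled reference cohort: panel genes are
standardized on the reference, per-subtype centroids are the per-gene
medians, and new samples are assigned to the centroid with the highest
Spearman correlation over the shared panel genes — the convention of the
PAM50 intrinsic-subtype classifier.  Rank correlation makes the calls
invariant to any monotone per-sample transform of expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExprMatrix

__all__ = ["GenePanel", "CentroidModel", "intersect_panel", "build_centroids", "classify",
           "SUBTYPE_ORDER"]

# fixed tie-break order for intrinsic subtypes
SUBTYPE_ORDER = ("Basal", "Her2", "LumA", "LumB", "Normal")


@dataclass(frozen=True)
class GenePanel:
    genes: tuple
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel gene symbols must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_file(cls, path, provenance=None):
        from .containers import read_gene_list
        return cls(tuple(read_gene_list(path)), provenance or str(path))


def intersect_panel(panel: GenePanel, annotation_genes) -> GenePanel:
    """Restrict a panel to genes present in an annotation; reports the missing."""
    present = set(annotation_genes)
    kept = tuple(g for g in panel.genes if g in present)
    missing = [g for g in panel.genes if g not in present]
    if missing:
        warnings.warn(
            f"{len(missing)} of {len(panel)} panel genes absent from the annotation: "
            f"{missing[:10]}", stacklevel=2)
    if len(panel) and len(kept) < 0.5 * len(panel):
        warnings.warn(
            f"panel intersection retains only {len(kept)}/{len(panel)} genes", stacklevel=2)
    return GenePanel(kept, provenance=f"{panel.provenance} ∩ annotation")


@dataclass
class CentroidModel:
    subtypes: tuple                     # label order (also the tie-break order)
    centroids: pd.DataFrame             # panel genes x subtypes, standardized space
    gene_mean: pd.Series                # training standardization parameters
    gene_sd: pd.Series

    def to_tsv(self, path) -> None:
        self.centroids.to_csv(path, sep="\t", index_label="gene")


def build_centroids(ref_expr, labels, panel: GenePanel) -> CentroidModel:
    """Fit per-gene standardization on the reference; centroid = per-subtype median."""
    mat = ref_expr if isinstance(ref_expr, ExprMatrix) else ExprMatrix(pd.DataFrame(ref_expr), "log2tpm")
    labels = pd.Series(labels).reindex(mat.samples)
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"subtype(s) with fewer than 2 reference samples: {list(small.index)}")
    sub = mat.subset_genes(panel.genes)
    if sub.shape[0] == 0:
        raise ValueError("no panel genes present in the reference matrix")
    mean = sub.data.mean(axis=1)
    sd = sub.data.std(axis=1, ddof=1)
    keep = sd > 0
    std = sub.data.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)

    known = [s for s in SUBTYPE_ORDER if s in set(labels)]
    extra = sorted(set(labels) - set(known))
    order = tuple(known + extra)
    cents = pd.DataFrame(
        {s: std.loc[:, (labels == s).to_numpy()].median(axis=1) for s in order}
    )
    return CentroidModel(subtypes=order, centroids=cents,
                         gene_mean=mean[keep], gene_sd=sd[keep])


def classify(expr, model: CentroidModel) -> pd.DataFrame:
    """Nearest-centroid calls by Spearman correlation over shared panel genes.

    Returns a DataFrame indexed by sample with columns ``label``,
    ``confidence`` (correlation with the winning centroid) and ``margin``
    (gap to the runner-up).  Samples constant over the panel are labeled
    ``unclassified``.
    """
    mat = expr if isinstance(expr, ExprMatrix) else ExprMatrix(pd.DataFrame(expr), "log2tpm")
    shared = [g for g in model.centroids.index if g in set(mat.genes)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} panel genes shared with the matrix; need >= 3")
    X = mat.data.loc[shared]
    C = model.centroids.loc[shared]

    rows = []
    for s in mat.samples:
        x = X[s].to_numpy(dtype=float)
        if np.allclose(x, x[0]):
            rows.append(("unclassified", np.nan, np.nan))
            continue
        cors = []
        for st in model.subtypes:
            r = sps.spearmanr(x, C[st].to_numpy()).statistic
            cors.append(-np.inf if np.isnan(r) else r)
        cors = np.asarray(cors)
        best = int(np.argmax(cors))   # argmax takes the first max: fixed-order tie-break
        runner = np.partition(cors, -2)[-2] if len(cors) > 1 else np.nan
        rows.append((model.subtypes[best], float(cors[best]), float(cors[best] - runner)))
    return pd.DataFrame(rows, index=mat.samples, columns=["label", "confidence", "margin"])
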