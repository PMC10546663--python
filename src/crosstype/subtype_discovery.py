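"""Unsupervised two-subtype discovery by NMF consensus clustering.

The factorization is the classical multiplicative-update NMF under the KL
(generalized Kullback-Leibler) divergence, run from many random starts.
Sample assignment is the argmax over the coefficient matrix H; stability is
summarized by a consensus matrix (fraction of runs co-assigning each sample
pair) and its cophenetic correlation, which drives rank selection.  Subtype
calls are accepted only for samples assigned consistently across several
gene-subset runs, mirroring the practice of repeating the factorization on
nested most-variable-gene subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .containers import ExprMatrix
from .preprocess import top_variable_genes

__all__ = [
    "NMFResult",
    "SubtypeResult",
    "nmf_factorize",
    "select_rank",
    "consensus_subtypes",
    "extract_metagenes",
    "validate_clustering",
]

_EPS = np.finfo(float).tiny


def _kl_div(X, WH):
    mask = X > 0
    val = np.sum(X[mask] * np.log(X[mask] / np.maximum(WH[mask], _EPS)))
    return float(val - X.sum() + WH.sum())


def _nmf_kl_run(X, rank, rng, max_iter=300, tol=1e-4, trajectory=None):
    """One Brunet multiplicative-update run; returns (W, H, objective).

    When ``trajectory`` is a list, the KL objective is appended after every
    iteration (used to assert the update is monotone non-increasing).
    """
    n, m = X.shape
    avg = np.sqrt(X.mean() / rank)
    W = avg * rng.random((n, rank)) + 1e-4
    H = avg * rng.random((rank, m)) + 1e-4
    prev = None
    for it in range(max_iter):
        WH = W @ H
        H *= (W.T @ (X / np.maximum(WH, _EPS))) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = W @ H
        W *= ((X / np.maximum(WH, _EPS)) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if trajectory is not None:
            trajectory.append(_kl_div(X, W @ H))
        if it % 10 == 9 or it == max_iter - 1:
            obj = _kl_div(X, W @ H)
            if prev is not None and abs(prev - obj) <= tol * max(abs(prev), 1.0):
                prev = obj
                break
            prev = obj
    return W, H, prev if prev is not None else _kl_div(X, W @ H)


def _consensus_cophenetic(consensus):
    """Cophenetic correlation of the consensus matrix (average linkage)."""
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    cond = squareform(d, checks=False)
    if np.allclose(cond, cond[0] if cond.size else 0.0):
        return 1.0  # degenerate: all dissimilarities equal
    Z = hierarchy.linkage(cond, method="average")
    coph, _ = hierarchy.cophenet(Z, cond)
    return float(coph)


@dataclass
class NMFResult:
    W: pd.DataFrame            # genes x rank, best-objective run
    H: pd.DataFrame            # rank x samples, best-objective run
    consensus: pd.DataFrame    # samples x samples co-assignment frequency
    cophenetic: float
    labels: pd.Series          # argmax-H assignment from the best run
    objective: float


def nmf_factorize(X, rank: int, n_runs: int = 30, seed: int = 0,
                  max_iter: int = 300, tol: float = 1e-4) -> NMFResult:
    """KL-divergence multiplicative-update NMF with a run-consensus summary."""
    data = X.data if isinstance(X, ExprMatrix) else pd.DataFrame(X)
    # single precision: the consensus/labels depend only on coarse structure,
    # and the multiplicative updates are memory-bandwidth bound
    arr = data.to_numpy(dtype=np.float32)
    if (arr < 0).any():
        raise ValueError("NMF input must be nonnegative")
    if not 1 <= rank < min(arr.shape):
        raise ValueError(f"rank {rank} out of range for shape {arr.shape}")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")

    ss = np.random.SeedSequence([int(seed), rank])
    children = ss.spawn(n_runs)
    n_samples = arr.shape[1]
    co = np.zeros((n_samples, n_samples))
    best = None
    for child in children:
        rng = np.random.default_rng(child)
        W, H, obj = _nmf_kl_run(arr, rank, rng, max_iter=max_iter, tol=tol)
        lab = H.argmax(axis=0)
        co += lab[:, None] == lab[None, :]
        if best is None or obj < best[2]:
            best = (W, H, obj)
    consensus = co / n_runs
    coph = _consensus_cophenetic(consensus.copy())
    W, H, obj = best
    return NMFResult(
        W=pd.DataFrame(W, index=data.index, columns=range(rank)),
        H=pd.DataFrame(H, index=range(rank), columns=data.columns),
        consensus=pd.DataFrame(consensus, index=data.columns, columns=data.columns),
        cophenetic=coph,
        labels=pd.Series(H.argmax(axis=0), index=data.columns, name="subtype"),
        objective=obj,
    )


def select_rank(X, ranks, n_runs: int = 30, seed: int = 0, **kw):
    """Choose the rank maximizing the cophenetic coefficient (ties: smallest)."""
    ranks = list(ranks)
    if not ranks:
        raise ValueError("empty rank list")
    coph = {}
    for r in ranks:
        coph[r] = nmf_factorize(X, r, n_runs=n_runs, seed=seed, **kw).cophenetic
    best = max(sorted(coph), key=lambda r: (coph[r], -r))
    return best, pd.Series(coph, name="cophenetic")


def _align_two_class(ref: np.ndarray, lab: np.ndarray) -> np.ndarray:
    """Flip binary labels if the swap agrees better with the reference."""
    agree = (ref == lab).sum()
    return lab if agree >= (ref == 1 - lab).sum() else 1 - lab


def _align_labels(ref: np.ndarray, lab: np.ndarray, k: int) -> np.ndarray:
    if k == 2:
        return _align_two_class(ref, lab)
    from scipy.optimize import linear_sum_assignment
    cost = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            cost[i, j] = -np.sum((ref == i) & (lab == j))
    _, col = linear_sum_assignment(cost)
    mapping = {int(col[i]): i for i in range(k)}
    return np.array([mapping[v] for v in lab])


@dataclass
class SubtypeResult:
    per_subset_labels: pd.DataFrame   # samples x subsets, aligned labels
    consensus_label: pd.Series        # label where consistent, <NA> otherwise
    consistent: pd.Series             # bool per sample
    metagenes: list
    nmf_results: dict                 # subset name -> NMFResult


def consensus_subtypes(expr, gene_subsets=None, rank: int = 2, n_runs: int = 30,
                       seed: int = 0, **kw) -> SubtypeResult:
    """Run NMF per gene subset and keep samples labeled identically in all runs.

    ``gene_subsets`` maps subset name -> gene list; the default is the full
    gene universe plus the top 5000/2000/1000/500 most variable genes
    (subsets larger than the universe are dropped).
    """
    mat = expr if isinstance(expr, ExprMatrix) else ExprMatrix(pd.DataFrame(expr), "log2tpm")
    if gene_subsets is None:
        gene_subsets = {"all": list(mat.genes)}
        for k in (5000, 2000, 1000, 500):
            if k < mat.shape[0]:
                gene_subsets[f"top{k}"] = top_variable_genes(mat, k)
    if not gene_subsets or any(len(g) == 0 for g in gene_subsets.values()):
        raise ValueError("gene subsets must be nonempty")

    results: dict[str, NMFResult] = {}
    aligned = {}
    ref = None
    for name, genes in gene_subsets.items():
        res = nmf_factorize(mat.subset_genes(genes), rank, n_runs=n_runs, seed=seed, **kw)
        results[name] = res
        lab = res.labels.to_numpy()
        if ref is None:
            ref = lab
            aligned[name] = lab
        else:
            aligned[name] = _align_labels(ref, lab, rank)
    per_subset = pd.DataFrame(aligned, index=mat.samples)
    consistent = per_subset.nunique(axis=1) == 1
    consensus_label = per_subset.iloc[:, 0].where(consistent).astype("Int64")

    first = next(iter(results))
    metagenes = extract_metagenes(results[first].W)
    return SubtypeResult(
        per_subset_labels=per_subset,
        consensus_label=consensus_label,
        consistent=consistent,
        metagenes=metagenes,
        nmf_results=results,
    )


def extract_metagenes(W) -> list:
    """Feature-gene scoring from the NMF basis (entropy-based).

    Each gene's basis row is normalized to a probability vector p; the score
    1 + sum_k p_k log2(p_k) / log2(rank) is 1 for a gene loading on a single
    factor and 0 for a perfectly flat gene.  Genes scoring above
    median + 3*MAD whose dominant factor loading is above that factor's
    median loading are returned.  All-zero rows are excluded.
    """
    Wdf = W if isinstance(W, pd.DataFrame) else pd.DataFrame(W)
    arr = Wdf.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("basis matrix must be nonnegative")
    rank = arr.shape[1]
    rowsum = arr.sum(axis=1)
    ok = rowsum > 0
    p = np.zeros_like(arr)
    p[ok] = arr[ok] / rowsum[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    score = np.where(ok, 1.0 + plogp.sum(axis=1) / np.log2(rank), -np.inf)

    finite = score[ok]
    med = np.median(finite)
    mad = np.median(np.abs(finite - med))
    cutoff = min(med + 3 * mad, np.nextafter(1.0, 0.0))
    dominant = arr.argmax(axis=1)
    col_median = np.median(arr, axis=0)
    keep = ok & (score > cutoff) & (arr[np.arange(len(arr)), dominant] > col_median[dominant])
    return list(Wdf.index[keep])


def _consensus_cluster_labels(points, k, n_resamples=1000, frac=0.8, seed=0):
    """Resampled consensus clustering (average-linkage inner clustering)."""
    rng = np.random.default_rng(seed)
    n = points.shape[0]
    co = np.zeros((n, n))
    both = np.zeros((n, n))
    m = max(int(round(frac * n)), k + 1)
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        Z = hierarchy.linkage(points[idx], method="average", metric="euclidean")
        lab = hierarchy.fcluster(Z, k, criterion="maxclust")
        same = lab[:, None] == lab[None, :]
        co[np.ix_(idx, idx)] += same
        both[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore"):
        consensus = np.where(both > 0, co / np.maximum(both, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    d = squareform(1.0 - consensus, checks=False)
    Z = hierarchy.linkage(d, method="average")
    return hierarchy.fcluster(Z, k, criterion="maxclust"), consensus


def validate_clustering(expr, genes=None, k: int = 2, reference=None,
                        n_resamples: int = 1000, n_boot: int = 200, seed: int = 0) -> dict:
    """Cross-method clustering agreement: k-means, consensus, hierarchical.

    Hierarchical clustering is accompanied by bootstrap co-clustering
    support (gene resampling).  Returns per-method labels, pairwise ARI and,
    if a reference labeling is supplied, ARI against it.
    """
    mat = expr if isinstance(expr, ExprMatrix) else ExprMatrix(pd.DataFrame(expr), "log2tpm")
    if genes is None:
        genes = top_variable_genes(mat, max(int(round(0.10 * mat.shape[0])), k))
    sub = mat.subset_genes(genes)
    pts = sub.data.to_numpy(dtype=float).T          # samples x genes
    n = pts.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")

    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(pts)
    cons, _ = _consensus_cluster_labels(pts, k, n_resamples=n_resamples, seed=seed)
    Z = hierarchy.linkage(pts, method="average", metric="euclidean")
    hc = hierarchy.fcluster(Z, k, criterion="maxclust")

    rng = np.random.default_rng(seed + 1)
    support = np.zeros((n, n))
    for _ in range(n_boot):
        gidx = rng.integers(0, pts.shape[1], pts.shape[1])
        Zb = hierarchy.linkage(pts[:, gidx], method="average", metric="euclidean")
        lb = hierarchy.fcluster(Zb, k, criterion="maxclust")
        support += lb[:, None] == lb[None, :]
    support /= n_boot

    labels = {"kmeans": km, "consensus": cons, "hierarchical": hc}
    methods = list(labels)
    ari = pd.DataFrame(1.0, index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            v = adjusted_rand_score(labels[a], labels[b])
            ari.loc[a, b] = ari.loc[b, a] = v
    report = {
        "labels": pd.DataFrame(labels, index=sub.samples),
        "pairwise_ari": ari,
        "bootstrap_support": pd.DataFrame(support, index=sub.samples, columns=sub.samples),
        "genes_used": list(genes),
    }
    if reference is not None:
        ref = pd.Series(reference).reindex(sub.samples)
        report["reference_ari"] = {m: adjusted_rand_score(ref, labels[m]) for m in methods}
    return report
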