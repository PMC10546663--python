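"""Resampled cross-species co-clustering homology test.

Each repeat draws a fixed-size reference of human tumors per intrinsic
subtype (plus the complete normal-like group), merges them with the full
canine cohort on the shared panel genes, clusters the joint row-scaled
matrix hierarchically, cuts the dendrogram at the minimum number of
clusters that maximally separates the two human anchor subtypes, and calls
a canine and a human subtype "matched" when a single cluster holds the
strict majority of both.  Match counts over repeats feed a Fisher exact
test; per-repeat classical MDS embeddings yield Mahalanobis distances
between subtype centers whose distributions are compared by Wilcoxon
rank-sum tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .containers import ExprMatrix
from .pam50 import GenePanel
from .preprocess import row_zscale

__all__ = [
    "SamplingScheme",
    "HomologyResult",
    "sample_reference",
    "dendrogram_separation_cut",
    "match_subtypes",
    "cocluster_once",
    "homology_experiment",
    "mds_embed",
    "mahalanobis_center_distance",
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
]


@dataclass(frozen=True)
class SamplingScheme:
    n_per_subtype: int = 60
    subtypes_sampled: tuple = ("LumA", "LumB", "Basal", "Her2")
    include_all_of: tuple = ("Normal",)
    n_repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_subtype <= 0:
            raise ValueError("n_per_subtype must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def sample_reference(human_labels, scheme: SamplingScheme, repeat_index: int) -> list:
    """Draw the human reference for one repeat: n per sampled subtype, all of
    the always-included subtypes.  Deterministic given (seed, repeat_index)."""
    labels = pd.Series(human_labels)
    rng = np.random.default_rng(np.random.SeedSequence([int(scheme.seed), int(repeat_index)]))
    chosen: list = []
    for st in scheme.subtypes_sampled:
        members = list(labels.index[labels == st])
        if len(members) < scheme.n_per_subtype:
            raise ValueError(
                f"subtype {st!r} has {len(members)} samples; need {scheme.n_per_subtype}")
        if len(members) == scheme.n_per_subtype:
            chosen.extend(members)
        else:
            chosen.extend(rng.choice(members, size=scheme.n_per_subtype, replace=False))
    for st in scheme.include_all_of:
        chosen.extend(labels.index[labels == st])
    return list(chosen)


def dendrogram_separation_cut(Z, leaf_ids, groupA, groupB, k_max: int | None = None):
    """Cut a dendrogram at the smallest k whose partition maximally separates
    two leaf groups.

    The separation score of a k-cluster partition is
    S(k) = (#A leaves in clusters holding no B + #B leaves in clusters
    holding no A) / (|A| + |B|).  For nested cuts S is non-decreasing in k
    and reaches 1 at the all-singleton partition, so the returned k is the
    minimum cluster count attaining the maximum separation.

    Returns ``(k, cluster_labels, S)`` with labels aligned to ``leaf_ids``.
    """
    leaf_ids = list(leaf_ids)
    n = len(leaf_ids)
    A = set(groupA)
    B = set(groupB)
    if not A or not B or A & B:
        raise ValueError("groups must be nonempty and disjoint")
    if not (A <= set(leaf_ids) and B <= set(leaf_ids)):
        raise ValueError("groups must be subsets of the tree leaves")
    if k_max is None:
        k_max = n
    if k_max < 2:
        raise ValueError("k_max must be >= 2")

    isA = np.array([x in A for x in leaf_ids])
    isB = np.array([x in B for x in leaf_ids])
    denom = isA.sum() + isB.sum()

    cuts = _nested_cuts(np.asarray(Z), n)
    best = None
    for k in range(2, k_max + 1):
        lab = cuts[n - k]
        nA = np.bincount(lab[isA], minlength=int(lab.max()) + 1)
        nB = np.bincount(lab[isB], minlength=int(lab.max()) + 1)
        S = (nA[nB == 0].sum() + nB[nA == 0].sum()) / denom
        if best is None or S > best[2] + 1e-12:
            best = (k, lab, S)
        if S >= 1.0 - 1e-12:
            break
    k, lab, S = best
    return k, pd.Series(lab, index=leaf_ids, name="cluster"), float(S)


def _nested_cuts(Z, n):
    """Nested partitions of a linkage tree, replayed from the merge order.

    ``cuts[m]`` holds consecutive cluster labels after m merges (n - m
    clusters), so ``cuts[n - k]`` is the k-cluster cut.  Replaying merges
    guarantees the cuts are nested, hence the separation score is monotone.
    """
    labels = np.arange(n)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    cuts = [labels.copy()]
    for i, (a, b, *_rest) in enumerate(Z):
        new = n + i
        leaves = members.pop(int(a)) + members.pop(int(b))
        members[new] = leaves
        labels[leaves] = new
        cuts.append(labels.copy())
    return [np.unique(c, return_inverse=True)[1] for c in cuts]


def match_subtypes(clusters, canine_labels, human_labels) -> list:
    """Pairs (canine subtype, human subtype) sharing a strict-majority cluster.

    A pair matches iff some single cluster contains more than half of ALL
    samples of the canine subtype and more than half of ALL samples of the
    human subtype.  Subtypes can also match nothing (a species-private
    cluster)."""
    clusters = pd.Series(clusters)
    cl = {}
    for name, labs in (("canine", pd.Series(canine_labels)), ("human", pd.Series(human_labels))):
        for st in labs.dropna().unique():
            members = labs.index[labs == st]
            counts = clusters.reindex(members).value_counts()
            total = len(members)
            majority = counts.index[counts > 0.5 * total]
            cl[(name, st)] = majority[0] if len(majority) else None
    pairs = []
    for (sp_c, st_c), cluster_c in cl.items():
        if sp_c != "canine" or cluster_c is None:
            continue
        for (sp_h, st_h), cluster_h in cl.items():
            if sp_h != "human" or cluster_h is None:
                continue
            if cluster_c == cluster_h:
                pairs.append((st_c, st_h))
    return pairs


def _as_log2(expr: ExprMatrix) -> ExprMatrix:
    if expr.unit == "log2tpm":
        return expr
    if expr.unit == "tpm":
        return expr.log2p1()
    raise ValueError(f"expected tpm or log2tpm input, got {expr.unit!r}")


def cocluster_once(canine_expr: ExprMatrix, human_ref_expr: ExprMatrix, panel: GenePanel,
                   canine_labels, human_labels, groupA_label: str = "Basal",
                   groupB_label: str = "LumA", linkage_method: str = "average",
                   mds_dims: int = 2) -> dict:
    """One joint clustering of the canine cohort with a human reference draw.

    Merges the two cohorts on the shared panel genes, row-scales the joint
    log2 matrix, clusters hierarchically (Euclidean, average linkage), cuts
    by :func:`dendrogram_separation_cut` anchored on two human subtypes, and
    records subtype matches, the MDS embedding and pairwise Mahalanobis
    center distances.
    """
    ca = _as_log2(canine_expr).subset_genes(panel.genes)
    hu = _as_log2(human_ref_expr).subset_genes(panel.genes)
    shared = [g for g in ca.genes if g in set(hu.genes)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared panel genes; need >= 3")
    joint = pd.concat([ca.data.loc[shared], hu.data.loc[shared]], axis=1)
    scaled = row_zscale(joint)
    pts = scaled.to_numpy(dtype=float).T
    samples = list(scaled.columns)

    Z = hierarchy.linkage(pts, method=linkage_method, metric="euclidean")
    human_labels = pd.Series(human_labels).reindex(hu.samples)
    canine_labels = pd.Series(canine_labels).reindex(ca.samples)
    groupA = list(human_labels.index[human_labels == groupA_label])
    groupB = list(human_labels.index[human_labels == groupB_label])
    k, clusters, S = dendrogram_separation_cut(Z, samples, groupA, groupB)
    matches = match_subtypes(clusters, canine_labels, human_labels)

    # MDS + Mahalanobis center distances between species-qualified groups
    from scipy.spatial.distance import pdist, squareform
    D = squareform(pdist(pts, metric="euclidean"))
    coords = mds_embed(D, mds_dims)
    group_of = {}
    for s, st in canine_labels.items():
        group_of[s] = f"c:{st}"
    for s, st in human_labels.items():
        group_of[s] = f"h:{st}"
    groups = pd.Series([group_of[s] for s in samples], index=samples)
    names = sorted(groups.unique())
    dists = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ga = coords[(groups == a).to_numpy()]
            gb = coords[(groups == b).to_numpy()]
            if len(ga) <= mds_dims or len(gb) <= mds_dims:
                continue
            dists[(a, b)] = mahalanobis_center_distance(ga, gb)
    return {
        "cut_k": k,
        "separation": S,
        "clusters": clusters,
        "matches": matches,
        "mds_coords": pd.DataFrame(coords, index=samples),
        "center_distances": dists,
    }


@dataclass
class HomologyResult:
    per_repeat: list                   # cocluster_once records (without coords)
    match_counts: pd.Series            # (canine, human) pair -> repeats matched
    fisher_table: np.ndarray           # 2x2 [pair1 matched/unmatched; pair2 ...]
    fisher_odds: float
    fisher_p: float
    distance_distributions: pd.DataFrame  # repeats x named pairs
    wilcoxon_p: dict                   # (pairA, pairB) -> two-sided p


def homology_experiment(canine_expr, canine_labels, human_expr, human_labels,
                        panel: GenePanel, scheme: SamplingScheme,
                        pair1: tuple | None = None, pair2: tuple | None = None,
                        groupA_label: str = "Basal", groupB_label: str = "LumA",
                        mds_dims: int = 2) -> HomologyResult:
    """Repeat the co-clustering over reference draws and aggregate statistics.

    ``pair1`` / ``pair2`` are the (canine subtype, human subtype) pairs whose
    match counts form the 2x2 Fisher table rows; they default to
    (majority canine subtype, groupA) and (other canine subtype, groupB).
    """
    human_labels = pd.Series(human_labels)
    canine_labels = pd.Series(canine_labels)
    c_subs = sorted(canine_labels.unique())
    if pair1 is None or pair2 is None:
        if len(c_subs) != 2:
            raise ValueError("pair1/pair2 must be given unless exactly two canine subtypes")
        pair1 = pair1 or (c_subs[0], groupA_label)
        pair2 = pair2 or (c_subs[1], groupB_label)

    records = []
    match_counter: dict[tuple, int] = {}
    dist_rows = []
    coverage: set = set()
    for r in range(scheme.n_repeats):
        ref_ids = sample_reference(human_labels, scheme, r)
        coverage.update(ref_ids)
        rec = cocluster_once(
            canine_expr, human_expr.subset_samples(ref_ids), panel,
            canine_labels, human_labels.reindex(ref_ids),
            groupA_label=groupA_label, groupB_label=groupB_label, mds_dims=mds_dims)
        for pair in rec["matches"]:
            match_counter[pair] = match_counter.get(pair, 0) + 1
        dist_rows.append({f"{a}|{b}": v for (a, b), v in rec["center_distances"].items()})
        records.append({k: rec[k] for k in ("cut_k", "separation", "matches")})

    sampled_pool = set(human_labels.index[human_labels.isin(scheme.subtypes_sampled)])
    uncovered = sampled_pool - coverage
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} reference samples never drawn across "
            f"{scheme.n_repeats} repeats", stacklevel=2)

    n = scheme.n_repeats
    m1 = match_counter.get(tuple(pair1), 0)
    m2 = match_counter.get(tuple(pair2), 0)
    table = np.array([[m1, n - m1], [m2, n - m2]])
    odds, p = fisher_exact_2x2(table)

    dist_df = pd.DataFrame(dist_rows)
    wilcoxon_p = {}
    cols = list(dist_df.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            x = dist_df[a].dropna().to_numpy()
            y = dist_df[b].dropna().to_numpy()
            if len(x) and len(y):
                wilcoxon_p[(a, b)] = wilcoxon_rank_sum(x, y)[1]
    return HomologyResult(
        per_repeat=records,
        match_counts=pd.Series(match_counter, dtype=int).sort_values(ascending=False)
        if match_counter else pd.Series(dtype=int),
        fisher_table=table,
        fisher_odds=odds,
        fisher_p=p,
        distance_distributions=dist_df,
        wilcoxon_p=wilcoxon_p,
    )


def mds_embed(distance_matrix, d: int) -> np.ndarray:
    """Classical (Torgerson) MDS of a symmetric zero-diagonal distance matrix.

    Coordinates are ordered by eigenvalue; if fewer than ``d`` positive
    eigenvalues exist the remaining columns are zero-padded with a warning.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8) or not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0.0) * 1e-12 if n else vals > 0
    r = int(pos.sum())
    if r < d:
        warnings.warn(f"only {r} positive eigenvalues; padding {d - r} zero columns",
                      stacklevel=2)
    coords = np.zeros((n, d))
    take = min(r, d)
    coords[:, :take] = vecs[:, :take] * np.sqrt(vals[:take])
    return coords


def mahalanobis_center_distance(coordsA, coordsB, ridge: float = 1e-8) -> float:
    """Mahalanobis distance between group centers under pooled covariance."""
    A = np.atleast_2d(np.asarray(coordsA, dtype=float))
    B = np.atleast_2d(np.asarray(coordsB, dtype=float))
    d = A.shape[1]
    if A.shape[0] < d + 1 or B.shape[0] < d + 1:
        raise ValueError(f"each group needs at least {d + 1} points in {d} dimensions")
    Sa = np.cov(A, rowvar=False)
    Sb = np.cov(B, rowvar=False)
    pooled = ((A.shape[0] - 1) * Sa + (B.shape[0] - 1) * Sb) / (A.shape[0] + B.shape[0] - 2)
    pooled = np.atleast_2d(pooled) + ridge * np.eye(d)
    diff = A.mean(axis=0) - B.mean(axis=0)
    try:
        sol = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"singular pooled covariance: {e}") from e
    return float(np.sqrt(diff @ sol))


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test by hypergeometric summation.

    The p-value sums, over all tables with the observed margins, the
    probabilities not exceeding that of the observed table (with a 1e-9
    relative slack against floating-point ties).  The odds ratio is the
    sample odds ratio ad/bc (inf when bc = 0).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = (int(x) for x in t.ravel())
    if min(a + b, c + d, a + c, b + d) == 0:
        return np.nan, 1.0
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = sps.hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    return odds, min(p, 1.0)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when n + m <= 12 and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if x.size + y.size <= 12 and no_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=True)
    return float(res.statistic), float(res.pvalue)
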