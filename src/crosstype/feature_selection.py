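"""All-relevant feature-gene selection for subtype classification.

Candidate genes come from pairwise differential expression between the
target subtype and each other subtype.  Each candidate pool is then passed
through Boruta: every round appends a shuffled "shadow" copy of each
feature, fits a random forest, and scores a real feature a hit when its
importance beats the best shadow importance; binomial tests with Bonferroni
correction confirm or reject features as rounds accumulate.  The outer loop
repeats Boruta with distinct sub-seeds on a stratified training split and
keeps genes confirmed at least ``freq_cutoff`` times, pooling selections
across the pairwise comparisons.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .containers import ExprMatrix
from .expression_stats import nb_wald_de, size_factors

__all__ = ["BorutaConfig", "FeatureSet", "pairwise_de_pools", "boruta_select",
           "stable_feature_genes"]


@dataclass(frozen=True)
class BorutaConfig:
    n_trees: int = 500
    max_rounds: int = 100
    min_rounds: int = 10      # evidence accumulated before any decision
    alpha: float = 0.01
    n_outer_repeats: int = 50
    freq_cutoff: int = 50
    train_fraction: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.freq_cutoff > self.n_outer_repeats:
            raise ValueError("freq_cutoff cannot exceed n_outer_repeats")
        if self.n_trees < 1 or self.max_rounds < 1:
            raise ValueError("n_trees and max_rounds must be positive")


@dataclass
class FeatureSet:
    genes: list
    frequency: pd.Series          # per selected gene, confirmations over repeats
    source_comparisons: dict      # comparison -> selected genes
    heldout_accuracy: float | None = None


def pairwise_de_pools(counts, labels, target_subtype, alpha: float = 0.05,
                      min_group: int = 3) -> dict:
    """DE gene pools between the target subtype and each other subtype.

    Pools use BH-adjusted p <= alpha with no fold-change cutoff (candidate
    generation, not final DE calling).
    """
    data = counts.data if isinstance(counts, ExprMatrix) else pd.DataFrame(counts)
    labels = pd.Series(labels).reindex(data.columns)
    others = sorted(set(labels.dropna().unique()) - {target_subtype})
    if not others:
        raise ValueError("need at least two subtypes")
    if (labels == target_subtype).sum() < min_group:
        raise ValueError(f"target subtype {target_subtype!r} has fewer than {min_group} samples")
    pools = {}
    for other in others:
        if (labels == other).sum() < min_group:
            raise ValueError(f"subtype {other!r} has fewer than {min_group} samples")
        keep = labels.isin([target_subtype, other])
        res = nb_wald_de(data.loc[:, keep.to_numpy()], labels[keep], fold_cutoff=1.0,
                         alpha=alpha)
        pools[f"{target_subtype}_vs_{other}"] = list(res.index[res.padj <= alpha])
    return pools


def boruta_select(X, y, config: BorutaConfig | None = None, seed: int | None = None) -> dict:
    """Boruta all-relevant selection against shadow features.

    Returns ``{"confirmed": [...], "tentative": [...], "rejected": [...]}``
    over the columns of ``X`` (samples x features).  Deterministic given the
    seed.
    """
    config = config or BorutaConfig()
    Xdf = pd.DataFrame(X)
    y = np.asarray(pd.Series(y))
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("y must contain at least two classes")
    if Xdf.shape[1] == 0:
        raise ValueError("no features to select from")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    features = list(Xdf.columns)
    undecided = list(features)
    confirmed: list = []
    rejected: list = []
    hits = {f: 0 for f in features}
    rounds_seen = {f: 0 for f in features}

    arr_full = Xdf.to_numpy(dtype=float)
    n_feat = len(features)
    for rnd in range(config.max_rounds):
        if not undecided:
            break
        # every feature (even already-decided ones) stays in the forest with
        # a full set of shadows: a shrinking pool would lower the max-shadow
        # bar over rounds and break the binomial(1/2) hit model
        shadow = arr_full.copy()
        for j in range(n_feat):
            shadow[:, j] = rng.permutation(shadow[:, j])
        rf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        ).fit(np.hstack([arr_full, shadow]), y)
        imp = rf.feature_importances_
        shadow_max = imp[n_feat:].max()
        undecided_set = set(undecided)
        for f, v in zip(features, imp[:n_feat]):
            if f in undecided_set:
                rounds_seen[f] += 1
                if v > shadow_max:
                    hits[f] += 1

        # binomial decisions, Bonferroni-corrected over the full feature
        # family (a shrinking denominator leaks false confirmations as
        # rejected features leave the family)
        if rnd >= config.min_rounds - 1:
            thr = config.alpha / len(features)
            still = []
            for f in undecided:
                n = rounds_seen[f]
                h = hits[f]
                p_hi = sps.binom.sf(h - 1, n, 0.5)   # P(>= h): evidence relevant
                p_lo = sps.binom.cdf(h, n, 0.5)      # P(<= h): evidence irrelevant
                if p_hi < thr:
                    confirmed.append(f)
                elif p_lo < thr:
                    rejected.append(f)
                else:
                    still.append(f)
            undecided = still
    return {
        "confirmed": [f for f in features if f in set(confirmed)],
        "tentative": [f for f in features if f in set(undecided)],
        "rejected": [f for f in features if f in set(rejected)],
    }


def _log_norm(counts_df: pd.DataFrame) -> pd.DataFrame:
    sf = size_factors(counts_df)
    return np.log2(counts_df.div(sf, axis=1) + 1.0)


def stable_feature_genes(counts, labels, target_subtype,
                         config: BorutaConfig | None = None,
                         pools: dict | None = None) -> FeatureSet:
    """Frequency-stable Boruta selection over pairwise DE pools.

    Splits samples into a stratified train/test partition, repeats Boruta
    ``n_outer_repeats`` times per pool on the training set, keeps genes
    confirmed at least ``freq_cutoff`` times, unions selections across the
    pairwise comparisons, and reports held-out nearest-centroid accuracy of
    the target-vs-rest dichotomy on the selected genes.
    """
    config = config or BorutaConfig()
    data = counts.data if isinstance(counts, ExprMatrix) else pd.DataFrame(counts)
    labels = pd.Series(labels).reindex(data.columns)
    if pools is None:
        pools = pairwise_de_pools(data, labels, target_subtype)

    rng = np.random.default_rng(config.seed)
    train_idx, test_idx = train_test_split(
        np.arange(data.shape[1]), train_size=config.train_fraction,
        stratify=labels.to_numpy(), random_state=int(rng.integers(0, 2**31 - 1)))
    logX = _log_norm(data)
    X_train = logX.iloc[:, train_idx]
    lab_train = labels.iloc[train_idx]

    freq: dict[str, int] = {}
    per_comparison: dict[str, list] = {}
    for comp, pool in pools.items():
        if not pool:
            per_comparison[comp] = []
            continue
        other = comp.split("_vs_")[-1]
        keep = lab_train.isin([target_subtype, other])
        Xc = X_train.loc[pool].T.loc[keep.to_numpy()]
        yc = (lab_train[keep] == target_subtype).astype(int).to_numpy()
        counts_conf: dict[str, int] = {g: 0 for g in pool}
        for r in range(config.n_outer_repeats):
            comp_key = zlib.crc32(comp.encode()) % (2**31)
            sub_seed = int(np.random.SeedSequence([config.seed, comp_key, r])
                           .generate_state(1)[0] % (2**31))
            sel = boruta_select(Xc, yc, config=config, seed=sub_seed)
            for g in sel["confirmed"]:
                counts_conf[g] += 1
        chosen = [g for g, c in counts_conf.items() if c >= config.freq_cutoff]
        per_comparison[comp] = chosen
        for g in chosen:
            freq[g] = max(freq.get(g, 0), counts_conf[g])

    genes = sorted(freq)
    if not genes:
        warnings.warn("no gene passed the frequency cutoff; empty feature set", stacklevel=2)
        return FeatureSet(genes=[], frequency=pd.Series(dtype=int),
                          source_comparisons=per_comparison, heldout_accuracy=None)

    # held-out evaluation: nearest-centroid target-vs-rest on the selected
    # genes.  The test samples are standardized per gene with the training
    # parameters first (the rank-based classifier expects relative
    # expression, not baseline-dominated absolute values).
    from .pam50 import GenePanel, build_centroids, classify
    panel = GenePanel(tuple(genes), provenance="stable feature genes")
    y_bin = labels.map(lambda s: target_subtype if s == target_subtype else "rest")
    ref = ExprMatrix(logX.iloc[:, train_idx], "log2tpm")
    model = build_centroids(ref, y_bin.iloc[train_idx], panel)
    test_z = (logX.loc[model.gene_mean.index].iloc[:, test_idx]
              .sub(model.gene_mean, axis=0).div(model.gene_sd, axis=0))
    calls = classify(ExprMatrix(test_z, "log2tpm"), model)
    acc = float((calls["label"].to_numpy() == y_bin.iloc[test_idx].to_numpy()).mean())
    return FeatureSet(
        genes=genes,
        frequency=pd.Series(freq).sort_values(ascending=False),
        source_comparisons=per_comparison,
        heldout_accuracy=acc,
    )
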