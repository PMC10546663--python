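"""Synthetic two-species mammary-tumor expression cohorts with known truth.

The generator emulates the data layout of a cross-species bulk RNA-seq
subtyping study: a canine cohort carrying two latent subtypes (a basal-like
subtype homologous to the human basal-like subtype, and a species-private
non-basal subtype) and a human cohort carrying the five intrinsic breast
cancer subtypes.  Counts are negative binomial around gene-specific means on
a log-normal baseline; subtype identity shifts a set of informative genes
(including a PAM50-like discriminative panel) by ``effect_size`` on the log2
scale; batch and species effects act as location-scale distortions on the
log2 means; hormone-receptor marker genes are pinned near configured FPKM
targets so that threshold-based receptor calls have a known truth.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExprMatrix, SampleMeta

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "simulate_cohort",
    "counts_to_fpkm",
    "fpkm_to_tpm",
    "default_two_species_config",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# Receptor subgroup -> (ESR1-like FPKM, PGR-like FPKM) targets.  Values are
# chosen to straddle the ER/PR positivity threshold of FPKM = 1 with a wide
# margin so that calls are unambiguous up to counting noise.
_DEFAULT_RECEPTOR_MEANS = {
    "ER-PR-": (0.15, 0.15),
    "ER-PR+": (0.15, 8.0),
    "ER+PR+": (8.0, 8.0),
    "ER+PR-": (8.0, 0.15),
}
# HER2 status -> ERBB2-like FPKM target (threshold 35).
_DEFAULT_HER2_MEANS = {"not_enriched": 12.0, "enriched": 90.0}


@dataclass
class SimConfig:
    """Configuration of a two-species synthetic cohort.

    ``subtypes_per_species`` maps species -> {subtype name -> n samples}.
    ``shared_axis`` names the homologous subtype pair as
    ``((species_a, subtype_a), (species_b, subtype_b))``; the two subtypes
    share their informative-gene signature.  ``receptor_config`` maps
    subtype -> {subgroup -> fraction of samples}, with subgroup strings in
    ``{"ER-PR-", "ER-PR+", "ER+PR+", "ER+PR-"}``.
    """

    n_genes: int = 2000
    n_panel_genes: int = 50
    subtypes_per_species: dict = field(default_factory=lambda: {
        "canine": {"cBLMT": 69, "cNBLMT": 74},
        "human": {"Basal": 80, "LumA": 80, "LumB": 70, "Her2": 70, "Normal": 27},
    })
    shared_axis: tuple = (("canine", "cBLMT"), ("human", "Basal"))
    effect_size: float = 2.0            # log2 shift on informative genes
    n_informative_per_subtype: int = 60  # non-panel informative genes per subtype
    # species-private subtypes (subtypes of the shared-axis species A that are
    # not the homologous subtype) diverge from every cross-species profile
    # more than the other species' subtypes differ among themselves
    private_effect_multiplier: float = 2.0
    batch_effects: dict = field(default_factory=lambda: {
        "canine": {"shift": 0.0, "scale": 1.0},
        "human": {"shift": 1.0, "scale": 1.1},
    })
    nb_dispersion: float = 0.15
    gene_length_range: tuple = (300, 10_000)  # bp, log-uniform
    library_size_range: tuple = (2_000_000, 4_000_000)
    receptor_config: dict = field(default_factory=lambda: {
        "cBLMT": {"ER-PR-": 0.29, "ER-PR+": 0.33, "ER+PR+": 0.29, "ER+PR-": 0.09},
        "cNBLMT": {"ER+PR+": 0.96, "ER+PR-": 0.04},
        "Basal": {"ER-PR-": 0.70, "ER+PR-": 0.30},
        "LumA": {"ER+PR+": 0.90, "ER+PR-": 0.10},
        "LumB": {"ER+PR+": 0.70, "ER+PR-": 0.30},
        "Her2": {"ER-PR-": 0.80, "ER-PR+": 0.20},
        "Normal": {"ER+PR+": 0.80, "ER-PR-": 0.20},
    })
    her2_enriched_frac: dict = field(default_factory=lambda: {"Her2": 0.95})
    receptor_means: dict = field(default_factory=lambda: dict(_DEFAULT_RECEPTOR_MEANS))
    her2_means: dict = field(default_factory=lambda: dict(_DEFAULT_HER2_MEANS))
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    seed: int = 0

    # ---- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_panel_genes <= 0 or self.n_panel_genes >= self.n_genes:
            raise ConfigError("n_panel_genes must be positive and smaller than n_genes")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if not self.subtypes_per_species:
            raise ConfigError("subtypes_per_species is empty")
        for sp, sub in self.subtypes_per_species.items():
            for name, n in sub.items():
                if n <= 0:
                    raise ConfigError(f"subtypes_per_species[{sp}][{name}] must be positive")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ConfigError("gene_length_range must be positive and ordered")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ConfigError("library_size_range must be positive and ordered")
        (sp_a, sub_a), (sp_b, sub_b) = self.shared_axis
        for sp, sub in [(sp_a, sub_a), (sp_b, sub_b)]:
            if sp not in self.subtypes_per_species or sub not in self.subtypes_per_species[sp]:
                raise ConfigError(f"shared_axis names unknown subtype {sp}/{sub}")
        for st, fracs in self.receptor_config.items():
            bad = [g for g in fracs if g not in _DEFAULT_RECEPTOR_MEANS]
            if bad:
                raise ConfigError(f"receptor_config[{st}] has unknown subgroups {bad}")
            if abs(sum(fracs.values()) - 1.0) > 1e-6:
                raise ConfigError(f"receptor_config[{st}] fractions must sum to 1")


@dataclass
class GroundTruth:
    """Planted truth for one simulated cohort."""

    subtype_label: pd.Series            # per sample
    informative_genes: dict             # subtype -> list of gene ids (panel + extra)
    panel_genes: list                   # PAM50-like discriminative panel
    homologous_pair: tuple              # (speciesA subtype, speciesB subtype)
    receptor_truth: pd.DataFrame        # per sample: ER, PR, HER2, subgroup
    marker_genes: dict                  # {"ER": gene, "PR": gene, "HER2": gene}
    gene_lengths: pd.Series             # bp per gene

    def __post_init__(self) -> None:
        universe = set(self.gene_lengths.index)
        for st, genes in self.informative_genes.items():
            if not set(genes) <= universe:
                raise ValueError(f"informative genes of {st} not in the gene universe")


def default_two_species_config(**overrides) -> SimConfig:
    """The standard study-shaped configuration, with keyword overrides."""
    cfg = SimConfig(**overrides)
    cfg.validate()
    return cfg


def recovery_study_config(seed: int = 0, n_genes: int = 800, effect_size: float = 2.0) -> SimConfig:
    """A 143-sample single-species two-subtype cohort for recovery studies.

    69 + 74 samples mirror the basal-like / non-basal split of a mid-sized
    mammary-tumor discovery cohort; one batch, so no location-scale
    distortion obscures the planted subtypes.
    """
    cfg = SimConfig(
        n_genes=n_genes,
        subtypes_per_species={"canine": {"cBLMT": 69, "cNBLMT": 74}},
        shared_axis=(("canine", "cBLMT"), ("canine", "cBLMT")),
        effect_size=effect_size,
        batch_effects={"canine": {"shift": 0.0, "scale": 1.0}},
        seed=seed,
    )
    cfg.validate()
    return cfg


def homology_study_config(seed: int = 0, **overrides) -> SimConfig:
    """Two-species cohort in the species-shift-corrected condition.

    The cross-species co-clustering statistic assumes location-scale species
    effects have already been removed (the batch-correction step of the
    pipeline), so this configuration generates both species on a common
    scale; the planted homologous pair is (cBLMT, Basal).
    """
    cfg = SimConfig(
        batch_effects={"canine": {"shift": 0.0, "scale": 1.0},
                       "human": {"shift": 0.0, "scale": 1.0}},
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{str(i).zfill(width)}" for i in range(n)]


def _allocate_signatures(cfg: SimConfig, rng: np.random.Generator, genes: list[str]):
    """Assign panel-gene blocks and extra informative genes per subtype.

    The homologous pair shares one signature; every other subtype gets a
    private block of panel genes plus private informative genes, mimicking a
    discriminative PAM50-like panel.
    """
    (sp_a, sub_a), (sp_b, sub_b) = cfg.shared_axis
    # signature owners: the shared axis counts once
    owners: list[tuple] = [("shared", None)]
    for sp, subs in cfg.subtypes_per_species.items():
        for st in subs:
            if (sp, st) in ((sp_a, sub_a), (sp_b, sub_b)):
                continue
            owners.append((sp, st))

    panel = list(rng.choice(genes[3:], size=cfg.n_panel_genes, replace=False))
    blocks = np.array_split(np.arange(cfg.n_panel_genes), len(owners))
    remaining = [g for g in genes[3:] if g not in set(panel)]
    extra_idx = rng.choice(len(remaining), size=cfg.n_informative_per_subtype * len(owners),
                           replace=False)

    informative: dict[str, list[str]] = {}
    for k, owner in enumerate(owners):
        block_genes = [panel[i] for i in blocks[k]]
        lo = k * cfg.n_informative_per_subtype
        extra = [remaining[i] for i in extra_idx[lo:lo + cfg.n_informative_per_subtype]]
        sig = block_genes + extra
        if owner[0] == "shared":
            informative[sub_a] = sig
            if sub_b != sub_a:
                informative[sub_b] = sig
        else:
            informative[owner[1]] = sig
    return panel, informative


def simulate_cohort(config: SimConfig) -> tuple[ExprMatrix, SampleMeta, GroundTruth]:
    """Draw a two-species cohort of NB counts with planted subtype structure.

    Returns the counts matrix (genes x samples), the sample metadata (species
    doubles as batch) and the planted :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _gene_ids(config.n_genes)
    marker_genes = {"ER": genes[0], "PR": genes[1], "HER2": genes[2]}
    gene_lengths = pd.Series(
        np.exp(rng.uniform(np.log(config.gene_length_range[0]),
                           np.log(config.gene_length_range[1]), config.n_genes)),
        index=genes, name="length_bp",
    ).round().clip(lower=1.0)

    panel, informative = _allocate_signatures(config, rng, genes)

    # sample bookkeeping -------------------------------------------------
    sample_ids, species_col, subtype_col = [], [], []
    for sp, subs in config.subtypes_per_species.items():
        for st, n in subs.items():
            for i in range(n):
                sample_ids.append(f"{sp[:2]}_{st}_{i:03d}")
                species_col.append(sp)
                subtype_col.append(st)
    n_samples = len(sample_ids)
    species_arr = np.array(species_col)
    subtype_arr = np.array(subtype_col)

    # receptor subgroup truth per sample ---------------------------------
    subgroup = np.empty(n_samples, dtype=object)
    her2 = np.empty(n_samples, dtype=object)
    for st in np.unique(subtype_arr):
        idx = np.where(subtype_arr == st)[0]
        fracs = config.receptor_config.get(st, {"ER+PR+": 1.0})
        names = sorted(fracs)
        counts = np.floor(np.array([fracs[g] for g in names]) * len(idx)).astype(int)
        while counts.sum() < len(idx):
            counts[int(np.argmax([fracs[g] for g in names]))] += 1
        assign = np.repeat(names, counts)[: len(idx)]
        subgroup[idx] = rng.permutation(assign)
        p_enriched = config.her2_enriched_frac.get(st, 0.02)
        her2[idx] = np.where(rng.random(len(idx)) < p_enriched, "enriched", "not_enriched")

    # log2 mean model ----------------------------------------------------
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    log2mu = np.tile(baseline[:, None], (1, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    (sp_a, sub_a), _ = config.shared_axis
    private_subtypes = {st for st in config.subtypes_per_species[sp_a] if st != sub_a}
    for st, sig in informative.items():
        cols = np.where(subtype_arr == st)[0]
        if cols.size == 0:
            continue
        rows = [gene_pos[g] for g in sig]
        eff = config.effect_size
        if st in private_subtypes:
            eff *= config.private_effect_multiplier
        log2mu[np.ix_(rows, cols)] += eff
    # species-private subtypes additionally carry a signed pattern across the
    # rest of the panel, making them orthogonal to every cross-species profile
    panel_rows = {gene_pos[g] for g in panel}
    for st in private_subtypes:
        cols = np.where(subtype_arr == st)[0]
        own = {gene_pos[g] for g in informative[st]}
        other_rows = sorted(panel_rows - own)
        signs = rng.choice([-1.0, 1.0], size=len(other_rows))
        pattern = config.effect_size * config.private_effect_multiplier * signs
        log2mu[np.ix_(other_rows, cols)] += pattern[:, None]
        informative[st] = informative[st] + [genes[i] for i in other_rows]

    # species/batch location-scale on the log2 scale ---------------------
    for sp, eff in config.batch_effects.items():
        cols = np.where(species_arr == sp)[0]
        if cols.size == 0:
            continue
        dev = log2mu[:, cols] - baseline[:, None]
        gene_shift = rng.normal(eff.get("shift", 0.0), 0.25 * abs(eff.get("shift", 0.0)) + 1e-12,
                                config.n_genes)
        log2mu[:, cols] = baseline[:, None] + eff.get("scale", 1.0) * dev + gene_shift[:, None]

    # receptor marker genes pinned to FPKM targets -----------------------
    rel = np.power(2.0, log2mu)                       # TPM-scale relative abundance
    lengths = gene_lengths.to_numpy()
    denom = (rel[3:] * lengths[3:, None]).sum(axis=0)  # markers excluded: negligible mass
    er_idx, pr_idx, her2_idx = (gene_pos[marker_genes[k]] for k in ("ER", "PR", "HER2"))
    er_target = np.array([config.receptor_means[g][0] for g in subgroup])
    pr_target = np.array([config.receptor_means[g][1] for g in subgroup])
    her2_target = np.array([config.her2_means[h] for h in her2])
    rel[er_idx] = er_target * denom / 1e9
    rel[pr_idx] = pr_target * denom / 1e9
    rel[her2_idx] = her2_target * denom / 1e9

    # counts -------------------------------------------------------------
    lib = rng.uniform(*config.library_size_range, n_samples)
    mass = rel * lengths[:, None]
    mean_counts = lib[None, :] * mass / mass.sum(axis=0, keepdims=True)
    disp = config.nb_dispersion
    # NB with mean m and variance m + disp*m^2
    n_param = 1.0 / disp
    p_param = n_param / (n_param + mean_counts)
    counts = rng.negative_binomial(n_param, np.clip(p_param, 1e-12, 1.0))

    expr = ExprMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids), "counts")
    meta = SampleMeta(pd.DataFrame(
        {"species": species_col, "batch": species_col, "subtype": subtype_col},
        index=pd.Index(sample_ids, name="sample"),
    ))
    receptor_truth = pd.DataFrame(
        {
            "ER": ["pos" if g.startswith("ER+") else "neg" for g in subgroup],
            "PR": ["pos" if g.endswith("PR+") else "neg" for g in subgroup],
            "HER2": her2,
            "subgroup": subgroup,
        },
        index=expr.samples,
    )
    truth = GroundTruth(
        subtype_label=pd.Series(subtype_arr, index=expr.samples, name="subtype"),
        informative_genes={st: list(sig) for st, sig in informative.items()},
        panel_genes=panel,
        homologous_pair=(config.shared_axis[0][1], config.shared_axis[1][1]),
        receptor_truth=receptor_truth,
        marker_genes=marker_genes,
        gene_lengths=gene_lengths,
    )
    return expr, meta, truth


def counts_to_fpkm(counts: ExprMatrix, lengths: pd.Series) -> ExprMatrix:
    """FPKM[g,s] = counts[g,s] * 1e9 / (length[g] * total_counts[s])."""
    if counts.unit != "counts":
        raise ValueError(f"counts_to_fpkm expects counts, got {counts.unit!r}")
    lens = lengths.reindex(counts.genes)
    if lens.isna().any():
        missing = list(lens.index[lens.isna()])[:5]
        raise ValueError(f"gene lengths missing for {missing}")
    if (lens <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.data.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero)}")
    fpkm = counts.data * 1e9
    fpkm = fpkm.div(lens, axis=0).div(totals, axis=1)
    return ExprMatrix(fpkm, "fpkm")


def fpkm_to_tpm(fpkm: ExprMatrix) -> ExprMatrix:
    """TPM[g,s] = FPKM[g,s] / sum_g FPKM[g,s] * 1e6; columns sum to 1e6."""
    if fpkm.unit != "fpkm":
        raise ValueError(f"fpkm_to_tpm expects fpkm, got {fpkm.unit!r}")
    colsum = fpkm.data.sum(axis=0)
    zero = colsum.index[colsum <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero FPKM: {list(zero)}")
    return ExprMatrix(fpkm.data.div(colsum, axis=1) * 1e6, "tpm")
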