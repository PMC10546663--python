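import numpy as np
import pandas as pd
import pytest

import crosstype as ct


@pytest.fixture(scope="session")
def two_species_cohort():
    """One seeded two-species cohort (with species batch effects) shared
    across read-only tests."""
    cfg = ct.default_two_species_config(seed=11)
    expr, meta, truth = ct.simulate_cohort(cfg)
    return cfg, expr, meta, truth


@pytest.fixture(scope="session")
def two_species_log2(two_species_cohort):
    _, expr, meta, truth = two_species_cohort
    fpkm = ct.counts_to_fpkm(expr, truth.gene_lengths)
    tpm = ct.fpkm_to_tpm(fpkm)
    return fpkm, tpm.log2p1(), meta, truth


@pytest.fixture(scope="session")
def homology_cohort():
    """Species-shift-corrected two-species cohort for cross-species tests."""
    cfg = ct.homology_study_config(seed=23)
    expr, meta, truth = ct.simulate_cohort(cfg)
    log2 = ct.fpkm_to_tpm(ct.counts_to_fpkm(expr, truth.gene_lengths)).log2p1()
    return log2, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def nb_counts(rng, mu, n_samples, dispersion=0.15):
    """NB count draws with mean mu (per gene) and variance mu + disp*mu^2."""
    mu = np.asarray(mu, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + mu[:, None])
    return rng.negative_binomial(n, p, (mu.size, n_samples))


def nb_two_group(rng, n_genes=2000, n_per_group=10, lfc=None, dispersion=0.15):
    """Two-group NB count matrix; ``lfc`` is the per-gene log2 fold change."""
    mu = np.exp(rng.normal(3.0, 1.2, n_genes))
    a = nb_counts(rng, mu, n_per_group, dispersion)
    mu_b = mu * np.power(2.0, np.zeros(n_genes) if lfc is None else np.asarray(lfc))
    b = nb_counts(rng, mu_b, n_per_group, dispersion)
    counts = pd.DataFrame(
        np.hstack([a, b]),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(2 * n_per_group)],
    )
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=counts.columns)
    return counts, groups
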