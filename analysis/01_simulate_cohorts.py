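#!/usr/bin/env python
"""Generate the synthetic two-species cohorts used by the downstream steps.

Writes, under scratch/cohorts/ (matrices are a few MB, so they live outside
the tracked results): counts / FPKM / TPM matrices (TSV), sample metadata,
and the planted ground truth (JSON), for
  - the two-species homology cohort (species-shift-corrected condition), and
  - one single-species 143-sample recovery cohort.
The downstream steps regenerate cohorts from the same seeds, so running this
script is optional; it exists to exercise the TSV/JSON external interface.
"""

import json
from pathlib import Path

import crosstype as ct

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohorts"
SEED = 2024


def dump_cohort(tag, cfg):
    expr, meta, truth = ct.simulate_cohort(cfg)
    fpkm = ct.counts_to_fpkm(expr, truth.gene_lengths)
    tpm = ct.fpkm_to_tpm(fpkm)
    d = OUT / tag
    d.mkdir(parents=True, exist_ok=True)
    expr.to_tsv(d / "counts.tsv")
    fpkm.to_tsv(d / "fpkm.tsv")
    tpm.to_tsv(d / "tpm.tsv")
    meta.to_tsv(d / "meta.tsv")
    truth_json = {
        "subtype_label": truth.subtype_label.to_dict(),
        "informative_genes": truth.informative_genes,
        "panel_genes": truth.panel_genes,
        "homologous_pair": list(truth.homologous_pair),
        "marker_genes": truth.marker_genes,
    }
    (d / "truth.json").write_text(json.dumps(truth_json, indent=2))
    print(f"{tag}: {expr.shape[0]} genes x {expr.shape[1]} samples -> {d}")


def main():
    dump_cohort("homology", ct.homology_study_config(seed=SEED))
    dump_cohort("recovery", ct.recovery_study_config(seed=SEED))


if __name__ == "__main__":
    main()
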