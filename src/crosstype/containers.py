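"""Core in-memory containers for expression data.

Expression is carried as a gene-by-sample :class:`pandas.DataFrame` wrapped in
:class:`ExprMatrix`, which records the unit the values are in (``counts``,
``fpkm``, ``tpm`` or ``log2tpm``).  Keeping the unit explicit lets every
downstream operation assert it receives the scale it was designed for instead
of silently mixing raw counts with log-transformed abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "fpkm", "tpm", "log2tpm")


@dataclass
class ExprMatrix:
    """Gene-by-sample expression matrix with an explicit unit tag.

    Parameters
    ----------
    data:
        DataFrame with genes as the index and samples as columns.
    unit:
        One of ``counts``, ``fpkm``, ``tpm``, ``log2tpm``.
    """

    data: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown expression unit {self.unit!r}; expected one of {VALID_UNITS}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExprMatrix":
        present = [g for g in genes if g in self.data.index]
        return ExprMatrix(self.data.loc[present], self.unit)

    def subset_samples(self, samples) -> "ExprMatrix":
        return ExprMatrix(self.data[list(samples)], self.unit)

    def log2p1(self) -> "ExprMatrix":
        """log2(TPM + 1) transform; identity if already on the log scale."""
        if self.unit == "log2tpm":
            return ExprMatrix(self.data.copy(), "log2tpm")
        if self.unit != "tpm":
            raise ValueError(f"log2p1 expects tpm input, got {self.unit!r}")
        return ExprMatrix(np.log2(self.data + 1.0), "log2tpm")

    # ---- plain-text round trip -------------------------------------------
    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, unit: str) -> "ExprMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, unit)


@dataclass
class SampleMeta:
    """Per-sample annotations: species, batch and optional labels."""

    table: pd.DataFrame  # index = sample ids; columns species, batch, subtype, ...
    required: tuple = field(default=("species", "batch"), repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in self.required if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample metadata lacks required columns: {missing}")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def column(self, name: str) -> pd.Series:
        return self.table[name]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "SampleMeta":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                out.append(g)
    return out
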