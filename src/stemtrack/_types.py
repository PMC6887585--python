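"""Core containers shared across the pipeline.

The pipeline passes around three light-weight objects: a labelled
genes x cells expression matrix with an explicit unit tag, a gene map
giving each gene a chromosome and a within-chromosome ordinal (the order
used for copy-number smoothing), and named gene-set collections backed by
the GMT format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: units an ExpressionMatrix may declare
VALID_UNITS = ("counts", "tpm", "census", "log")


@dataclass
class ExpressionMatrix:
    """Genes x cells numeric matrix with a declared unit.

    ``data`` is indexed by gene name, columns are cell ids.  ``unit`` is one
    of :data:`VALID_UNITS`; downstream stages check it so that e.g. CNV
    smoothing is never run on raw counts by accident.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def cells(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_cells(self, cells) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, cells], self.unit)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[genes], self.unit)


def make_gene_map(genes, chromosomes, ordinals) -> pd.DataFrame:
    """Assemble a gene map frame (columns gene, chromosome, ordinal)."""
    gm = pd.DataFrame(
        {"gene": list(genes), "chromosome": list(chromosomes), "ordinal": list(ordinals)}
    )
    return gm


def sort_gene_map(gene_map: pd.DataFrame) -> pd.DataFrame:
    """Return the gene map sorted by (chromosome, ordinal) — the CNV order."""
    return gene_map.sort_values(["chromosome", "ordinal"], kind="mergesort").reset_index(drop=True)


@dataclass
class SignatureSet:
    """Named gene sets (GMT-backed): mapping set name -> member genes."""

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> list:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list:
        return list(self.sets)

    def add(self, name: str, genes, description: str = "") -> None:
        self.sets[name] = list(genes)
        self.descriptions[name] = description
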