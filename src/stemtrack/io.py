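"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices travel either as TSV (gene rows, cell columns, header
row of cell ids) or as MatrixMarket ``.mtx`` with ``.rows`` / ``.cols``
sidecar files carrying the gene and cell names.  Gene maps and per-cell
tables are TSV; gene sets use the GMT convention (set name, description,
then member genes, tab-separated).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._types import ExpressionMatrix, SignatureSet


# ---------------------------------------------------------------- matrices

def write_expression_tsv(expr: ExpressionMatrix, path: str) -> str:
    expr.data.to_csv(path, sep="\t", index_label="gene")
    return path


def read_expression_tsv(path: str, unit: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return ExpressionMatrix(df, unit)


def write_expression_mtx(expr: ExpressionMatrix, path: str) -> str:
    """Write ``path`` (.mtx) plus ``path + '.rows'`` / ``'.cols'`` sidecars."""
    sp = scipy.sparse.csr_matrix(expr.data.to_numpy())
    scipy.io.mmwrite(path, sp)
    if not path.endswith(".mtx"):
        path = path + ".mtx"
    with open(path + ".rows", "w") as fh:
        fh.write("\n".join(map(str, expr.genes)) + "\n")
    with open(path + ".cols", "w") as fh:
        fh.write("\n".join(map(str, expr.cells)) + "\n")
    return path


def read_expression_mtx(path: str, unit: str) -> ExpressionMatrix:
    mat = scipy.io.mmread(path)
    if not path.endswith(".mtx"):
        path = path + ".mtx"
    with open(path + ".rows") as fh:
        genes = [ln.strip() for ln in fh if ln.strip()]
    with open(path + ".cols") as fh:
        cells = [ln.strip() for ln in fh if ln.strip()]
    dense = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
    return ExpressionMatrix(pd.DataFrame(dense, index=genes, columns=cells), unit)


# ------------------------------------------------------------- gene tables

def write_gene_map(gene_map: pd.DataFrame, path: str) -> str:
    gene_map.to_csv(path, sep="\t", index=False)
    return path


def read_gene_map(path: str) -> pd.DataFrame:
    gm = pd.read_csv(path, sep="\t")
    required = {"gene", "chromosome", "ordinal"}
    if not required.issubset(gm.columns):
        raise ValueError(f"gene map must have columns {sorted(required)}")
    return gm


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> str:
    df.to_csv(path, sep="\t", index=index)
    return path


def read_table(path: str, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# -------------------------------------------------------------------- GMT

def write_gmt(signatures: SignatureSet, path: str) -> str:
    with open(path, "w") as fh:
        for name in signatures:
            desc = signatures.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *map(str, signatures[name])]) + "\n")
    return path


def read_gmt(path: str) -> SignatureSet:
    sig = SignatureSet()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sig.add(parts[0], [g for g in parts[2:] if g], description=parts[1])
    return sig


def read_gene_list(path: str) -> list:
    """One gene per line (used for housekeeping lists and catalogs)."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_gene_list(genes, path: str) -> str:
    with open(path, "w") as fh:
        fh.write("\n".join(map(str, genes)) + "\n")
    return path


def ensure_dir(directory: str) -> str:
    os.makedirs(directory, exist_ok=True)
    return directory
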