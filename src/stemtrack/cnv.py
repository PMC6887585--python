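"""Expression-inferred copy-number profiles and tumor-cell screening.

Copy number is approximated per cell as the sliding average of
log2-transformed TPM over a window of flanking genes ordered along each
chromosome, then centered across cells.  Cells are separated into tumor
and nontumor by hierarchical clustering of their smoothed profiles
together with a control-derived reference pseudo-cell: the cluster holding
the reference — and any cluster whose profiles stay close to it — is
called normal, the rest tumor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from ._types import ExpressionMatrix, sort_gene_map

log = logging.getLogger(__name__)


@dataclass
class CnvParams:
    """Knobs of the CNV screen.

    ``window`` is the number of flanking genes: the moving average spans
    the gene itself plus up to ``window // 2`` genes on each side,
    truncated at chromosome boundaries.  ``normal_tolerance`` is the
    multiple of the reference group's deviation statistic below which a
    cluster is still considered normal.
    """

    window: int = 100
    log_pseudocount: float = 1.0
    reference_profile: np.ndarray | None = None
    linkage: str = "ward"
    n_cut: int = 2
    normal_tolerance: float = 2.0
    require_tumor: bool = False

    def validate(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.n_cut < 2:
            raise ValueError("n_cut must be >= 2")


@dataclass
class CnvMatrix:
    """Smoothed, cross-cell-centered log2 profiles (genes x cells).

    ``gene_means`` stores the per-gene cross-cell mean of the *uncentered*
    smoothed profile, so external profiles (e.g. a control reference) can
    be placed on the same centered scale.
    """

    values: pd.DataFrame
    gene_means: pd.Series = field(default=None)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    def center_external(self, profile: pd.Series) -> pd.Series:
        """Bring an uncentered smoothed profile onto this matrix's scale."""
        return profile.reindex(self.genes) - self.gene_means


def _smooth_chromosome(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0, truncated at the block edges."""
    half = window // 2
    n = block.shape[0]
    cs = np.concatenate([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)[:, None]


def smoothed_profiles(tpm: ExpressionMatrix, gene_map: pd.DataFrame,
                      params: CnvParams | None = None) -> pd.DataFrame:
    """Sliding-average log2(TPM + pseudocount), per chromosome, uncentered."""
    params = params or CnvParams()
    params.validate()
    gm = sort_gene_map(gene_map)
    missing = set(tpm.genes) - set(gm["gene"])
    if missing:
        raise ValueError(f"{len(missing)} genes in the matrix are absent from the gene map")
    gm = gm[gm["gene"].isin(set(tpm.genes))]

    out_blocks, out_genes = [], []
    for chrom, sub in gm.groupby("chromosome", sort=True):
        if len(sub) < 2:
            log.warning("chromosome %s has < 2 mapped genes; excluded from CNV", chrom)
            continue
        block = np.log2(tpm.data.loc[sub["gene"]].to_numpy(float) + params.log_pseudocount)
        out_blocks.append(_smooth_chromosome(block, params.window))
        out_genes.extend(sub["gene"].tolist())
    if not out_blocks:
        raise ValueError("no chromosome had enough genes for smoothing")
    sm = np.concatenate(out_blocks, axis=0)
    return pd.DataFrame(sm, index=out_genes, columns=tpm.cells)


def infer_cnv(tpm: ExpressionMatrix, gene_map: pd.DataFrame,
              params: CnvParams | None = None) -> CnvMatrix:
    """Smoothed log2 profiles centered across all cells."""
    if tpm.unit != "tpm":
        raise ValueError(f"CNV inference expects TPM input, got unit {tpm.unit!r}")
    sm = smoothed_profiles(tpm, gene_map, params)
    gene_means = sm.mean(axis=1)
    return CnvMatrix(values=sm.sub(gene_means, axis=0), gene_means=gene_means)


def reference_vector(control_tpm: ExpressionMatrix, gene_map: pd.DataFrame,
                     params: CnvParams | None = None) -> pd.Series:
    """Average smoothed (uncentered) profile of a set of control cells."""
    if control_tpm.shape[1] == 0:
        raise ValueError("empty control set")
    sm = smoothed_profiles(control_tpm, gene_map, params)
    return sm.mean(axis=1)


def classify_tumor_cells(cnv: CnvMatrix, reference: pd.Series,
                         params: CnvParams | None = None) -> pd.Series:
    """Label each cell ``tumor`` or ``normal``.

    The centered profiles plus the (re-centered) reference pseudo-cell are
    hierarchically clustered (Euclidean, ``params.linkage``) and cut into
    ``params.n_cut`` groups.  A group is normal when it contains the
    reference, or when the mean squared deviation of its *mean profile*
    from the reference profile is within ``params.normal_tolerance`` times
    the reference group's own value; everything else is tumor.  Averaging
    the group profile before comparing suppresses per-cell noise while a
    shared copy-number segment survives it.
    """
    params = params or CnvParams()
    params.validate()
    ref_centered = cnv.center_external(reference)
    if ref_centered.isna().any():
        raise ValueError("reference profile does not cover all CNV genes")

    X = np.column_stack([cnv.values.to_numpy(float), ref_centered.to_numpy(float)]).T
    Z = sch.linkage(X, method=params.linkage, metric="euclidean")
    groups = sch.fcluster(Z, t=params.n_cut, criterion="maxclust")
    ref_group = groups[-1]
    groups = groups[:-1]

    # deviation of each group's mean profile from the reference
    V = cnv.values.to_numpy(float)
    ref_arr = ref_centered.to_numpy(float)
    ref_members = groups == ref_group

    def group_stat(members):
        return float(((V[:, members].mean(axis=1) - ref_arr) ** 2).mean())

    base = group_stat(ref_members) if ref_members.any() else 0.0
    labels = np.empty(len(groups), dtype=object)
    for g in np.unique(groups):
        members = groups == g
        if g == ref_group or group_stat(members) <= params.normal_tolerance * base + 1e-12:
            labels[members] = "normal"
        else:
            labels[members] = "tumor"
    if (labels == "normal").all():
        if params.require_tumor:
            raise ValueError("no tumor cells detected: every cluster matches the control")
        log.warning("no tumor cells detected: every cluster matches the control")
    return pd.Series(labels, index=cnv.cells, name="cnv_call")
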