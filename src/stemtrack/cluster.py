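"""Density-peak clustering, differential expression and enrichment.

Cells are clustered in a low-dimensional embedding by the density-peak
rule: a cell is a cluster peak when its local density rho and its distance
delta to the nearest denser cell both exceed thresholds; every other cell
inherits the label of its nearest denser neighbor, visited in order of
decreasing density.  Cluster markers come from a rank-sum z statistic
(|z| > 2.58 corresponds to two-sided P < 0.01), and marker lists are
annotated by upper-tail hypergeometric enrichment with Benjamini-Hochberg
control across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def z_critical(p: float = 0.01) -> float:
    """Two-sided standard-normal critical value at level ``p``."""
    return float(scipy.stats.norm.isf(p / 2.0))


@dataclass
class ClusterParams:
    """Density-peak clustering knobs.

    ``rho_threshold`` / ``delta_threshold`` select the peaks; their useful
    scale depends on the embedding, so the peak table (rho, delta per
    cell) is always returned for inspection.  ``d_c_percentile`` sets the
    density cutoff distance as a percentile of all pairwise distances.
    """

    rho_threshold: float = 2.0
    delta_threshold: float = 4.0
    density_kernel: str = "cutoff"  # {"cutoff", "gaussian"}
    d_c_percentile: float = 2.0
    kernel_bandwidth: float | None = None
    embedding_dims: int = 2
    embedding_method: str = "pca"
    ordering_gene_min_mean: float = 0.1
    dispersion_margin: float = 1.0
    dispersion_bins: int = 20

    def validate(self) -> None:
        if self.rho_threshold <= 0 or self.delta_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.embedding_dims < 2:
            raise ValueError("embedding_dims must be >= 2")


# ------------------------------------------------------ gene selection

def select_ordering_genes(log_expr: pd.DataFrame,
                          params: ClusterParams | None = None) -> list:
    """Genes with mean expression above threshold and high dispersion.

    Dispersion is the variance/mean ratio of de-logged expression; a gene
    qualifies when its dispersion exceeds the median of its mean-expression
    bin by at least ``dispersion_margin`` median absolute deviations.
    """
    params = params or ClusterParams()
    X = log_expr.to_numpy(float)
    mean_log = X.mean(axis=1)
    delog = np.power(2.0, X) - 1.0
    m = delog.mean(axis=1)
    v = delog.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(m > 0, v / m, 0.0)

    candidate = mean_log > params.ordering_gene_min_mean
    if not candidate.any():
        raise ValueError(
            f"no gene has mean log-expression > {params.ordering_gene_min_mean}; "
            f"max observed {mean_log.max():.4f}"
        )
    # dispersion baseline fit over all genes so the mean filter acts as a
    # pure intersection (raising min_mean can only shrink the selection)
    sel = np.zeros(X.shape[0], dtype=bool)
    order = np.argsort(mean_log, kind="mergesort")
    bins = np.array_split(order, min(params.dispersion_bins, len(order)))
    for b in bins:
        if len(b) == 0:
            continue
        med = np.median(disp[b])
        mad = np.median(np.abs(disp[b] - med))
        sel[b] = disp[b] > med + params.dispersion_margin * mad
    sel &= (disp > 0) & candidate
    genes = list(log_expr.index[sel])
    if not genes:
        raise ValueError(
            "dispersion filter selected no genes; lower dispersion_margin "
            f"(candidates: {candidate.sum()}, median dispersion {np.median(disp[candidate]):.3g})"
        )
    return genes


def embed_cells(log_expr: pd.DataFrame, params: ClusterParams | None = None,
                seed: int = 0) -> np.ndarray:
    """Deterministic cell embedding (PCA) used for clustering."""
    params = params or ClusterParams()
    pca = PCA(n_components=min(params.embedding_dims, min(log_expr.shape) - 1),
              random_state=seed, svd_solver="full")
    return pca.fit_transform(log_expr.to_numpy(float).T)


# ------------------------------------------------- density-peak rule

def density_peak_cluster(embedding: np.ndarray,
                         params: ClusterParams | None = None):
    """Cluster points by local density and distance to denser neighbors.

    Returns ``(labels, peak_table)``; ``peak_table`` has rho, delta and the
    peak flag per point (the decision-plot data).  Density ties are broken
    by smallest index, which makes the denser-neighbor relation a strict
    order and the assignment deterministic.
    """
    params = params or ClusterParams()
    params.validate()
    X = np.asarray(embedding, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    D = squareform(pdist(X))
    pos = D[D > 0]
    d_c = np.percentile(pos, params.d_c_percentile) if pos.size else 1.0
    if params.density_kernel == "cutoff":
        rho = (D < d_c).sum(axis=1) - 1.0
    elif params.density_kernel == "gaussian":
        bw = params.kernel_bandwidth or d_c
        rho = np.exp(-((D / bw) ** 2)).sum(axis=1) - 1.0
    else:
        raise ValueError(f"unknown density kernel {params.density_kernel!r}")

    # strict density order: (rho, -index) descending; ties -> smaller index denser
    order = np.lexsort((np.arange(n), -rho))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)

    delta = np.empty(n)
    nearest_denser = np.full(n, -1)
    for i in range(n):
        denser = rank < rank[i]
        if not denser.any():
            delta[i] = D.max() if n > 1 else 0.0
        else:
            cand = np.flatnonzero(denser)
            j = cand[np.argmin(D[i, cand])]
            delta[i] = D[i, j]
            nearest_denser[i] = j

    is_peak = (rho > params.rho_threshold) & (delta > params.delta_threshold)
    # degenerate geometry: all points identical -> one cluster at the densest point
    if not is_peak.any() and np.allclose(D, 0.0):
        is_peak[order[0]] = True
    if not is_peak.any():
        table = pd.DataFrame({"rho": rho, "delta": delta, "is_peak": is_peak})
        raise ValueError(
            "no density peaks found: thresholds too strict for this embedding; "
            f"decision data: max rho {rho.max():.3g}, max delta {delta.max():.3g}\n"
            f"{table.describe().to_string()}"
        )

    labels = np.full(n, -1)
    next_label = 0
    for i in order:  # decreasing density
        if is_peak[i]:
            labels[i] = next_label
            next_label += 1
        else:
            labels[i] = labels[nearest_denser[i]] if nearest_denser[i] >= 0 else 0
    table = pd.DataFrame({"rho": rho, "delta": delta, "is_peak": is_peak,
                          "label": labels})
    return labels, table


# ------------------------------------------ differential expression

def _ranksum_z(X: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Tie-corrected normal approximation of the Wilcoxon rank-sum statistic.

    Positive z means the group expresses higher than the rest.  Matches
    the textbook large-sample form: z = (R1 - n1(N+1)/2) / sigma with the
    tie-corrected sigma.
    """
    n = X.shape[1]
    n1 = int(in_group.sum())
    n2 = n - n1
    ranks = scipy.stats.rankdata(X, axis=1)
    r1 = ranks[:, in_group].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    tie_term = np.zeros(X.shape[0])
    for g in range(X.shape[0]):
        _vals, cnt = np.unique(X[g], return_counts=True)
        tie_term[g] = np.sum(cnt**3 - cnt)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma2 = np.maximum(sigma2, 1e-300)
    return (r1 - mu) / np.sqrt(sigma2)


def _twocomp_z(X: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Dropout-aware z: Welch z on the expressed (nonzero) component means."""
    z = np.zeros(X.shape[0])
    for g in range(X.shape[0]):
        a = X[g, in_group]
        b = X[g, ~in_group]
        a = a[a > 0]
        b = b[b > 0]
        if a.size < 2 or b.size < 2:
            continue
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        if se > 0:
            z[g] = (a.mean() - b.mean()) / se
    return z


def differential_expression(expr: pd.DataFrame, cluster_labels,
                            z_cut: float = 2.58, engine: str = "ranksum",
                            min_cluster_size: int = 3) -> pd.DataFrame:
    """Cluster-vs-rest differential expression.

    Returns one row per (gene, cluster) with the signed z, the direction
    and the significance flag at ``|z| > z_cut``.  Clusters smaller than
    ``min_cluster_size`` are skipped with a warning.
    """
    labels = np.asarray(cluster_labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters for differential expression")
    stat = {"ranksum": _ranksum_z, "twocomp": _twocomp_z}.get(engine)
    if stat is None:
        raise ValueError(f"unknown DE engine {engine!r}")
    X = expr.to_numpy(float)
    rows = []
    for cl in uniq:
        in_group = labels == cl
        if in_group.sum() < min_cluster_size:
            log.warning("cluster %s has < %d cells; skipped", cl, min_cluster_size)
            continue
        z = stat(X, in_group)
        for gene, zi in zip(expr.index, z):
            rows.append((gene, cl, zi, "up" if zi > 0 else "down", abs(zi) > z_cut))
    return pd.DataFrame(rows, columns=["gene", "cluster", "z", "direction", "significant"])


# -------------------------------------------------------- enrichment

def hypergeometric_enrichment(gene_list, signature_sets, universe,
                              fdr_cut: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list against sets.

    BH-adjusted across the tested sets; sets disjoint from the universe
    are skipped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(gene_list) & universe
    if set(gene_list) - universe:
        raise ValueError("gene_list must be a subset of the universe")
    rows = []
    for name in signature_sets.names():
        members = set(signature_sets[name]) & universe
        if not members:
            log.warning("set %s disjoint from universe; skipped", name)
            continue
        overlap = sorted(hits & members)
        k, M, n, N = len(overlap), len(universe), len(members), len(hits)
        p = float(scipy.stats.hypergeom.sf(k - 1, M, n, N))
        rows.append((name, k, n, N, M, p, ",".join(map(str, overlap))))
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "list_size", "universe", "p", "overlap_genes"]
    )
    if len(table):
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["fdr"] < fdr_cut
        table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    return table
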