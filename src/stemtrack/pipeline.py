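"""High-level workflow: from a normalized matrix to the stem-to-invasion path.

The trajectory workflow mirrors the published analysis chain: cluster
cells, select ordering genes by differential expression between clusters,
learn a principal tree on the standardized ordering-gene matrix, root it
at the leaf with maximal stemness, and refine once — cells at the far end
of pseudotime are re-clustered to expose the fate split, their
differential genes are added to the ordering set, and the tree is refit.
The refinement step matters because genes that separate the terminal
fates are weakly variable over the whole population and easy to miss in a
single selection pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import cluster as stcluster
from . import trajectory as sttraj

log = logging.getLogger(__name__)


def standardize_genes(log_expr: pd.DataFrame) -> pd.DataFrame:
    """Center and scale every gene to unit variance (constant genes -> 0)."""
    mu = log_expr.mean(axis=1)
    sd = log_expr.std(axis=1)
    return log_expr.sub(mu, axis=0).div(sd + 1e-9, axis=0)


def ordering_genes_by_de(log_expr: pd.DataFrame, labels, z_cut: float = 2.58,
                         cap: int = 400) -> list:
    """Ordering genes = genes differentially expressed between cell groups.

    For each gene the maximal |z| over group-vs-rest rank-sum tests is
    taken; genes above ``z_cut`` are kept, strongest first, up to ``cap``.
    """
    de = stcluster.differential_expression(log_expr, labels, z_cut=z_cut)
    best = de.groupby("gene")["z"].agg(lambda z: float(np.max(np.abs(z))))
    sig = best[best > z_cut].sort_values(ascending=False)
    genes = list(sig.index[:cap])
    if not genes:
        raise ValueError("no differentially expressed ordering genes found")
    return genes


@dataclass
class TrajectoryResult:
    """Rooted trajectory plus the ordering genes and labels that built it."""

    trajectory: sttraj.Trajectory
    ordering_genes: list
    initial_clusters: pd.Series


def fit_progression_trajectory(log_expr: pd.DataFrame, csc_scores: pd.Series,
                               seed: int = 0, n_clusters: int = 6,
                               n_dims: int = 4, n_nodes: int = 12,
                               knn_smooth: int = 15, smoothness: float = 2.0,
                               prune_min_cells: int = 15,
                               refine: bool = True,
                               late_quantile: float = 0.6,
                               n_fate_groups: int = 3) -> TrajectoryResult:
    """Learn a rooted principal tree from normalized log expression.

    ``log_expr`` should already have nuisance effects (patient offsets)
    removed.  ``csc_scores`` (per-cell stemness) choose the root leaf.
    With ``refine`` enabled, cells beyond the ``late_quantile`` of the
    first-pass pseudotime are re-clustered into ``n_fate_groups`` groups
    and their differential genes augment the ordering set before a final
    refit.
    """
    emb = PCA(n_components=min(10, min(log_expr.shape) - 1), random_state=seed,
              svd_solver="full").fit_transform(log_expr.to_numpy(float).T)
    k = min(n_clusters, log_expr.shape[1] // 10) or 2
    clusters = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(emb)
    clusters = pd.Series(clusters, index=log_expr.columns, name="cluster")

    genes = ordering_genes_by_de(log_expr, clusters.to_numpy())

    def fit(gene_set):
        traj = sttraj.learn_trajectory(
            standardize_genes(log_expr.loc[gene_set]), n_dims=n_dims, seed=seed,
            n_nodes=n_nodes, smoothness=smoothness, knn_smooth=knn_smooth,
            prune_min_cells=prune_min_cells,
        )
        return sttraj.root_trajectory(traj, csc_scores)

    rooted = fit(genes)

    if refine:
        pt = rooted.pseudotime
        late = pt[pt >= pt.quantile(late_quantile)].index
        if len(late) >= 10 * n_fate_groups:
            z_late = standardize_genes(log_expr).loc[:, late]
            y = PCA(n_components=3, random_state=seed,
                    svd_solver="full").fit_transform(z_late.to_numpy(float).T)
            fate = KMeans(n_clusters=n_fate_groups, random_state=seed,
                          n_init=10).fit_predict(y)
            try:
                extra = ordering_genes_by_de(log_expr.loc[:, late], fate, cap=200)
            except ValueError:
                extra = []
            if extra:
                genes = sorted(set(genes) | set(extra))
                rooted = fit(genes)
        else:
            log.info("too few late cells for terminal refinement; skipped")

    return TrajectoryResult(trajectory=rooted, ordering_genes=genes,
                            initial_clusters=clusters)
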