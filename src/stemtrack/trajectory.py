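"""Principal-tree trajectories, pseudotime, branch tests and path extraction.

Cells are embedded by PCA and summarized by a small set of tree nodes:
k-means centroids refined by alternating a minimum-spanning-tree step with
a centroid update that pulls each node toward its softly assigned cells
and its tree neighbors.  Cells project onto the nearest tree edge;
segments between branch points and leaves define discrete states, and
pseudotime is the geodesic distance from a chosen root leaf along the
tree.  Branch-dependent expression is tested by comparing shared versus
branch-specific natural-spline fits of expression on pseudotime with a
Gaussian likelihood-ratio statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class Trajectory:
    """A principal tree with per-cell projections.

    ``tree`` is an undirected acyclic connected networkx graph whose nodes
    carry a ``pos`` attribute (coordinates in the embedding); ``cell_edge``
    and ``cell_offset`` give each cell's projected edge and the position
    along it in [0, 1]; ``states`` labels cells by tree segment; after
    rooting, ``pseudotime`` holds geodesic distances from the root.
    """

    tree: nx.Graph
    cells: pd.Index
    embedding: np.ndarray
    cell_edge: list
    cell_offset: np.ndarray
    cell_coords: np.ndarray
    states: pd.Series
    segments: dict  # state id -> list of edges
    root: int | None = None
    pseudotime: pd.Series | None = None

    @property
    def branch_points(self) -> list:
        return [n for n in self.tree.nodes if self.tree.degree[n] >= 3]

    @property
    def leaves(self) -> list:
        return [n for n in self.tree.nodes if self.tree.degree[n] == 1]

    def check_tree(self) -> None:
        if not nx.is_connected(self.tree):
            raise AssertionError("principal graph is not connected")
        if len(self.tree.edges) != len(self.tree.nodes) - 1:
            raise AssertionError("principal graph contains a cycle")


@dataclass
class PathSpec:
    """An ordered root-to-terminal sequence of states and its cells."""

    states: list
    cells: list
    pseudotime: pd.Series

    def __post_init__(self) -> None:
        pt = self.pseudotime.loc[self.cells].to_numpy()
        if np.any(np.diff(pt) < -1e-9):
            raise AssertionError("path cells must be ordered by nondecreasing pseudotime")


# ----------------------------------------------------------- learning

def _edge_length(tree: nx.Graph, u, v) -> float:
    return float(np.linalg.norm(tree.nodes[u]["pos"] - tree.nodes[v]["pos"]))


def _mst_edges(centroids: np.ndarray):
    D = cdist(centroids, centroids)
    mst = minimum_spanning_tree(D).toarray()
    return [(int(i), int(j)) for i, j in zip(*np.nonzero(mst))]


def _build_tree(centroids: np.ndarray, edges) -> nx.Graph:
    g = nx.Graph()
    for i, c in enumerate(centroids):
        g.add_node(i, pos=np.asarray(c, float))
    for u, v in edges:
        g.add_edge(u, v, length=float(np.linalg.norm(centroids[u] - centroids[v])))
    return g


def project_cells(tree: nx.Graph, X: np.ndarray):
    """Nearest point on any tree edge for each row of ``X``.

    On edges that end in a leaf the projection extrapolates beyond the
    leaf (offset outside [0, 1]) so cells past the end of the tree keep
    their ordering instead of collapsing onto the last node.

    Returns ``(edges, offsets, coords, dists)``.
    """
    edges = list(tree.edges)
    best_d = np.full(X.shape[0], np.inf)
    best_e = np.zeros(X.shape[0], dtype=int)
    best_t = np.zeros(X.shape[0])
    for k, (u, v) in enumerate(edges):
        a = tree.nodes[u]["pos"]
        b = tree.nodes[v]["pos"]
        ab = b - a
        denom = float(ab @ ab)
        if denom > 0:
            t = ((X - a) @ ab) / denom
            lo = -np.inf if tree.degree[u] == 1 else 0.0
            hi = np.inf if tree.degree[v] == 1 else 1.0
            t = np.clip(t, lo, hi)
        else:
            t = np.zeros(X.shape[0])
        proj = a + t[:, None] * ab
        d = np.linalg.norm(X - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_e[better] = k
        best_t[better] = t[better]
    coords = np.empty_like(X)
    cell_edges = []
    for i in range(X.shape[0]):
        u, v = edges[best_e[i]]
        a, b = tree.nodes[u]["pos"], tree.nodes[v]["pos"]
        coords[i] = a + best_t[i] * (b - a)
        cell_edges.append((u, v))
    return cell_edges, best_t, coords, best_d


def _segment_edges(tree: nx.Graph) -> dict:
    """Split edges into segments delimited by branch points and leaves."""
    if len(tree.edges) == 0:
        return {}
    eg = nx.Graph()
    eg.add_nodes_from(frozenset(e) for e in tree.edges)
    for node in tree.nodes:
        if tree.degree[node] <= 2:
            inc = [frozenset(e) for e in tree.edges(node)]
            for i in range(len(inc)):
                for j in range(i + 1, len(inc)):
                    eg.add_edge(inc[i], inc[j])
    comps = [sorted(tuple(sorted(e)) for e in comp) for comp in nx.connected_components(eg)]
    comps.sort(key=lambda c: c[0])
    return {f"S{i + 1}": [tuple(e) for e in comp] for i, comp in enumerate(comps)}


def _states_from_segments(segments: dict, cell_edges, cells: pd.Index) -> pd.Series:
    edge_to_state = {}
    for state, edges in segments.items():
        for e in edges:
            edge_to_state[frozenset(e)] = state
    return pd.Series([edge_to_state[frozenset(e)] for e in cell_edges], index=cells,
                     name="state")


def learn_trajectory(log_expr: pd.DataFrame, n_nodes: int | None = None,
                     n_dims: int = 2, seed: int = 0, max_iter: int = 50,
                     smoothness: float = 1.0, prune_min_cells: int = 5,
                     knn_smooth: int | None = 15, tol: float = 1e-4) -> Trajectory:
    """Fit an unrooted principal tree to cells (genes x cells input).

    PCA to ``n_dims`` (optionally followed by k-nearest-neighbor averaging
    of the embedding, which suppresses per-cell noise before the tree is
    fit), k-means initialization of ``n_nodes`` centroids (default
    ``max(10, n_cells // 10)``), then alternating MST construction and
    centroid updates (soft cell assignment plus a smoothness pull toward
    tree neighbors).  Leaf segments holding fewer than ``prune_min_cells``
    cells are pruned.
    """
    n_cells = log_expr.shape[1]
    if n_cells < 20:
        raise ValueError("need at least 20 cells to learn a trajectory")
    if n_nodes is None:
        n_nodes = max(10, n_cells // 10)
    n_nodes = min(n_nodes, n_cells)

    pca = PCA(n_components=min(n_dims, min(log_expr.shape) - 1), random_state=seed,
              svd_solver="full")
    X = pca.fit_transform(log_expr.to_numpy(float).T)
    if knn_smooth and knn_smooth > 1:
        from sklearn.neighbors import NearestNeighbors

        k = min(knn_smooth, n_cells)
        _, idx = NearestNeighbors(n_neighbors=k).fit(X).kneighbors(X)
        X = X[idx].mean(axis=1)

    km = KMeans(n_clusters=n_nodes, random_state=seed, n_init=10)
    centroids = km.fit(X).cluster_centers_.copy()

    scale = float(np.linalg.norm(X.std(axis=0)) + 1e-12)
    converged = False
    for _it in range(max_iter):
        edges = _mst_edges(centroids)
        d2 = cdist(X, centroids) ** 2
        sigma2 = max(np.mean(np.min(d2, axis=1)), 1e-12)
        R = np.exp(-(d2 - d2.min(axis=1, keepdims=True)) / (2.0 * sigma2))
        R /= R.sum(axis=1, keepdims=True)
        deg = np.zeros(n_nodes)
        nb_sum = np.zeros_like(centroids)
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
            nb_sum[u] += centroids[v]
            nb_sum[v] += centroids[u]
        w = R.sum(axis=0)
        new = (R.T @ X + smoothness * nb_sum) / (w + smoothness * deg)[:, None]
        move = np.max(np.linalg.norm(new - centroids, axis=1))
        centroids = new
        if move < tol * scale:
            converged = True
            break
    if not converged:
        warnings.warn("principal tree did not fully converge; returning best iterate",
                      stacklevel=2)
    tree = _build_tree(centroids, _mst_edges(centroids))

    # prune low-support leaf segments (noise twigs around branch points)
    while True:
        cell_edges, offs, coords, _ = project_cells(tree, X)
        segments = _segment_edges(tree)
        states = _states_from_segments(segments, cell_edges, pd.RangeIndex(n_cells))
        counts = states.value_counts()
        branch_nodes = {n for n in tree.nodes if tree.degree[n] >= 3}
        removable = None
        for state, seg_edges in sorted(segments.items()):
            if len(segments) <= 1:
                break
            nodes = {n for e in seg_edges for n in e}
            has_leaf = any(tree.degree[n] == 1 for n in nodes)
            if has_leaf and counts.get(state, 0) < prune_min_cells:
                removable = nodes - branch_nodes
                break
        if not removable:
            break
        tree.remove_nodes_from(removable)
        if len(tree.nodes) == 0:
            raise RuntimeError("pruning removed the whole tree")

    cell_edges, offs, coords, _ = project_cells(tree, X)
    segments = _segment_edges(tree)
    states = _states_from_segments(segments, cell_edges, log_expr.columns)
    traj = Trajectory(
        tree=tree, cells=log_expr.columns, embedding=X, cell_edge=cell_edges,
        cell_offset=offs, cell_coords=coords, states=states, segments=segments,
    )
    traj.check_tree()
    return traj


# ------------------------------------------------------------- rooting

def _leaf_of_state(traj: Trajectory, state: str):
    nodes = {n for e in traj.segments[state] for n in e}
    leaves = sorted(n for n in nodes if traj.tree.degree[n] == 1)
    return leaves[0] if leaves else None


def cell_pseudotime(traj: Trajectory, root: int) -> pd.Series:
    """Geodesic distance of each cell's projection from ``root``.

    Projections extrapolated beyond a leaf keep their signed offset;
    cells that fall before the root end are shifted so the minimum
    pseudotime is 0.
    """
    dist = nx.single_source_dijkstra_path_length(traj.tree, root, weight="length")
    pt = np.empty(len(traj.cells))
    for i, ((u, v), t) in enumerate(zip(traj.cell_edge, traj.cell_offset)):
        L = traj.tree.edges[u, v]["length"]
        if t > 1.0:  # beyond leaf v
            pt[i] = dist[v] + (t - 1.0) * L if v != root else -(t - 1.0) * L
        elif t < 0.0:  # beyond leaf u
            pt[i] = dist[u] + (-t) * L if u != root else t * L
        else:
            pt[i] = min(dist[u] + t * L, dist[v] + (1.0 - t) * L)
    pt -= min(pt.min(), 0.0)
    return pd.Series(pt, index=traj.cells, name="pseudotime")


def root_trajectory(traj: Trajectory, csc_scores: pd.Series,
                    force_leaf: int | None = None) -> Trajectory:
    """Root the tree at the leaf whose segment has maximal median CSC score.

    ``force_leaf`` overrides the automatic choice.  Pseudotime is
    (re)computed as geodesic distance from the root.
    """
    if force_leaf is not None:
        if traj.tree.degree[force_leaf] != 1:
            raise ValueError(f"node {force_leaf} is not a leaf")
        root = force_leaf
    else:
        scores = csc_scores.reindex(traj.cells)
        if scores.isna().any():
            raise ValueError("CSC scores must cover every cell")
        best, best_med = None, -np.inf
        for state in sorted(traj.segments):
            leaf = _leaf_of_state(traj, state)
            if leaf is None:
                continue
            members = traj.states == state
            if not members.any():
                continue
            med = float(scores[members].median())
            if med > best_med + 1e-12:
                best, best_med = state, med
            elif abs(med - best_med) <= 1e-12 and best is not None:
                warnings.warn(f"leaf-segment CSC tie between {best} and {state}; "
                              f"keeping {best}", stacklevel=2)
        if best is None:
            raise ValueError("no leaf segment contains cells; cannot root")
        root = _leaf_of_state(traj, best)
    pt = cell_pseudotime(traj, root)
    rooted = replace(traj, root=root, pseudotime=pt)
    rooted.check_tree()
    return rooted


# ------------------------------------------------------- branch tests

def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    Columns: 1, x, then K-2 truncated-cubic contrasts for K knots.
    Reproduces any linear function exactly.
    """
    x = np.asarray(x, float)
    knots = np.unique(np.asarray(knots, float))
    K = len(knots)
    if K < 2:
        raise ValueError("need at least 2 distinct knots")

    def d(k):
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[-1], 0.0) ** 3
        return num / (knots[-1] - knots[k])

    cols = [np.ones_like(x), x]
    if K > 2:
        dK1 = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dK1)
    return np.column_stack(cols)


def default_knots(x: np.ndarray, n_internal: int = 3) -> np.ndarray:
    qs = np.linspace(0, 100, n_internal + 2)
    return np.percentile(np.asarray(x, float), qs)


def smooth_curve(values: pd.Series | np.ndarray, pseudotime: pd.Series | np.ndarray,
                 n_internal_knots: int = 3, grid_size: int = 100):
    """Least-squares natural-spline fit of values on pseudotime.

    Returns ``(grid, fitted)`` with the curve evaluated on a uniform
    ``grid_size``-point grid over the pseudotime range.
    """
    y = np.asarray(values, float)
    x = np.asarray(pseudotime, float)
    if x.size < 8:
        raise ValueError("need at least 8 cells to fit a smooth curve")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate pseudotime: all values equal")
    knots = default_knots(x, n_internal_knots)
    B = natural_spline_basis(x, knots)
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    grid = np.linspace(x.min(), x.max(), grid_size)
    return grid, natural_spline_basis(grid, knots) @ coef


@dataclass
class BranchTest:
    """Likelihood-ratio test of branch-dependent expression per gene."""

    table: pd.DataFrame  # gene, statistic, p, q, significant
    branches: tuple = field(default=("A", "B"))
    q_cut: float = 1e-4


def branch_test_core(expr: pd.DataFrame, pseudotime: np.ndarray,
                     branch_labels: np.ndarray, q_cut: float = 1e-4,
                     n_internal_knots: int = 3) -> BranchTest:
    """Shared vs branch-specific spline fits, Gaussian LR statistic.

    ``expr`` is genes x cells over the cells of the two branches;
    the statistic is n*ln(RSS_shared / RSS_branch), chi-square with the
    interaction degrees of freedom, BH-adjusted across genes.
    """
    x = np.asarray(pseudotime, float)
    labels = np.asarray(branch_labels)
    branches = np.unique(labels)
    if len(branches) != 2:
        raise ValueError(f"need exactly 2 branches, got {list(branches)}")
    n = x.size
    knots = default_knots(x, n_internal_knots)
    B = natural_spline_basis(x, knots)
    ind = (labels == branches[1]).astype(float)
    B_full = np.column_stack([B, B * ind[:, None]])

    Y = expr.to_numpy(float).T  # cells x genes
    fit0, *_ = np.linalg.lstsq(B, Y, rcond=None)
    rss0 = ((Y - B @ fit0) ** 2).sum(axis=0)
    fit1, *_ = np.linalg.lstsq(B_full, Y, rcond=None)
    rss1 = ((Y - B_full @ fit1) ** 2).sum(axis=0)

    eps = 1e-300
    stat = n * np.log(np.maximum(rss0, eps) / np.maximum(rss1, eps))
    stat = np.maximum(stat, 0.0)
    df = B.shape[1]
    p = scipy.stats.chi2.sf(stat, df)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"gene": expr.index, "statistic": stat, "p": p, "q": q, "significant": q < q_cut}
    )
    return BranchTest(table=table, branches=tuple(branches), q_cut=q_cut)


def downstream_branches(traj: Trajectory, branch_point: int) -> dict:
    """Cells downstream of a branch point, grouped by child subtree.

    Requires a rooted trajectory; the subtree containing the root is
    excluded.  Returns ``{child_node: cell mask (pd.Series)}``.
    """
    if traj.root is None:
        raise ValueError("trajectory must be rooted first")
    if traj.tree.degree[branch_point] < 3:
        raise ValueError(f"node {branch_point} is not a branch point")
    cut = traj.tree.copy()
    cut.remove_node(branch_point)
    comps = list(nx.connected_components(cut))
    out = {}
    for comp in comps:
        if traj.root in comp:
            continue
        # edges fully inside the component, plus those linking it to the branch point
        members = np.array([
            (frozenset(e) <= comp | {branch_point}) and (set(e) & comp)
            for e in traj.cell_edge
        ], dtype=bool)
        child = min(set(comp) & set(traj.tree.neighbors(branch_point)))
        out[child] = pd.Series(members, index=traj.cells)
    return out


def branch_dependent_test(log_expr: pd.DataFrame, traj: Trajectory,
                          branch_point: int, q_cut: float = 1e-4,
                          min_cells: int = 10) -> BranchTest:
    """Branch-dependent expression at a branch point of a rooted tree."""
    groups = downstream_branches(traj, branch_point)
    if len(groups) > 2:
        sizes = {c: int(m.sum()) for c, m in groups.items()}
        keep = sorted(sizes, key=lambda c: -sizes[c])[:2]
        log.warning("branch point %s has %d descendants; testing the two largest",
                    branch_point, len(groups))
        groups = {c: groups[c] for c in keep}
    if len(groups) < 2:
        raise ValueError("branch point has fewer than 2 non-root descendants")
    (ca, ma), (cb, mb) = sorted(groups.items())
    if ma.sum() < min_cells or mb.sum() < min_cells:
        raise ValueError("each downstream branch needs >= "
                         f"{min_cells} cells (got {int(ma.sum())}, {int(mb.sum())})")
    mask = (ma | mb).to_numpy()
    cells = traj.cells[mask]
    labels = np.where(ma.to_numpy()[mask], f"via{ca}", f"via{cb}")
    pt = traj.pseudotime.loc[cells].to_numpy()
    return branch_test_core(log_expr.loc[:, cells], pt, labels, q_cut=q_cut)


# ------------------------------------------------------ path extraction

def state_graph(traj: Trajectory) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(traj.segments)
    items = sorted(traj.segments.items())
    for i, (sa, ea) in enumerate(items):
        na = {n for e in ea for n in e}
        for sb, eb in items[i + 1:]:
            nb = {n for e in eb for n in e}
            if na & nb:
                g.add_edge(sa, sb)
    return g


def root_state(traj: Trajectory) -> str:
    if traj.root is None:
        raise ValueError("trajectory must be rooted first")
    for state, edges in sorted(traj.segments.items()):
        if any(traj.root in e for e in edges):
            return state
    raise AssertionError("root node belongs to no segment")


def extract_path(traj: Trajectory, target_state: str) -> PathSpec:
    """Unique tree path of states from the root state to ``target_state``."""
    if target_state not in traj.segments:
        raise ValueError(f"unknown state {target_state!r}")
    sg = state_graph(traj)
    states = nx.shortest_path(sg, root_state(traj), target_state)
    members = traj.states.isin(states)
    cells = traj.pseudotime[members].sort_values(kind="mergesort").index.tolist()
    return PathSpec(states=list(states), cells=cells, pseudotime=traj.pseudotime)


def terminal_state_by_score(traj: Trajectory, scores: pd.Series) -> str:
    """Leaf-containing state with maximal median score (e.g. invasive end).

    The root state is excluded unless it is the only state (a path-shaped
    tree collapses to a single segment, which then serves as the path).
    """
    best, best_med = None, -np.inf
    start = root_state(traj)
    for state in sorted(traj.segments):
        if state == start or _leaf_of_state(traj, state) is None:
            continue
        members = traj.states == state
        if not members.any():
            continue
        med = float(scores.reindex(traj.cells)[members].median())
        if med > best_med:
            best, best_med = state, med
    if best is None:
        if (traj.states == start).any():
            log.warning("tree has a single populated segment; using the root state "
                        "as the terminal state")
            return start
        raise ValueError("no terminal state with cells found")
    return best
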