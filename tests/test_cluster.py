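"""Density-peak clustering, rank-sum DE and hypergeometric enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from stemtrack import cluster as stcluster
from stemtrack._types import SignatureSet


# ------------------------------------------------------ gene selection

def test_constant_genes_never_selected(rng):
    X = rng.normal(3, 1, (30, 20))
    X[:5] = 2.0  # constant rows
    df = pd.DataFrame(X, index=[f"g{i}" for i in range(30)])
    try:
        genes = stcluster.select_ordering_genes(df)
    except ValueError:
        genes = []
    assert not set(genes) & {f"g{i}" for i in range(5)}


def test_raising_min_mean_never_enlarges_selection(rng):
    X = np.abs(rng.normal(2, 2, (100, 40)))
    df = pd.DataFrame(X, index=[f"g{i}" for i in range(100)])
    lo = set(stcluster.select_ordering_genes(
        df, stcluster.ClusterParams(ordering_gene_min_mean=0.1)))
    hi = set(stcluster.select_ordering_genes(
        df, stcluster.ClusterParams(ordering_gene_min_mean=2.0)))
    assert hi <= lo


def test_bimodal_genes_selected(rng):
    """Planted bimodal genes stand out of a quiet graded background."""
    n_cells = 60
    base = rng.uniform(0.5, 6.0, 100)
    X = rng.normal(base[:, None], 0.2, (100, n_cells))
    bimodal = rng.choice(100, 6, replace=False)
    for g in bimodal:
        X[g, : n_cells // 2] += 3.0
    df = pd.DataFrame(X, index=[f"g{i}" for i in range(100)])
    genes = stcluster.select_ordering_genes(df)
    assert {f"g{i}" for i in bimodal} <= set(genes)


# ------------------------------------------------- density-peak rule

def _blobs(rng, n=100, sep=10.0):
    a = rng.normal([0, 0], 1.0, (n, 2))
    b = rng.normal([sep, 0], 1.0, (n, 2))
    return np.vstack([a, b]), np.repeat([0, 1], n)


def test_two_blobs_two_clusters(rng):
    for _ in range(3):
        X, truth = _blobs(rng)
        labels, table = stcluster.density_peak_cluster(X)
        assert len(np.unique(labels)) == 2
        assert adjusted_rand_score(truth, labels) == 1.0
        assert table["is_peak"].sum() == 2


def test_identical_points_single_cluster():
    X = np.ones((12, 3))
    labels, _ = stcluster.density_peak_cluster(X)
    assert len(np.unique(labels)) == 1


def test_too_strict_thresholds_raise(rng):
    X = rng.normal(0, 1, (30, 2))
    with pytest.raises(ValueError, match="thresholds too strict"):
        stcluster.density_peak_cluster(
            X, stcluster.ClusterParams(rho_threshold=1e9, delta_threshold=1e9))


def brute_force_density_peak(X, rho_threshold, delta_threshold, d_c):
    """Independent O(n^2) implementation of the assignment rule."""
    n = len(X)
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    rho = (D < d_c).sum(1) - 1.0
    order = sorted(range(n), key=lambda i: (-rho[i], i))
    rank = {i: r for r, i in enumerate(order)}
    delta = np.empty(n)
    parent = [-1] * n
    for i in range(n):
        denser = [j for j in range(n) if rank[j] < rank[i]]
        if not denser:
            delta[i] = D.max()
        else:
            j = min(denser, key=lambda j: D[i, j])
            delta[i], parent[i] = D[i, j], j
    labels = [-1] * n
    nxt = 0
    for i in order:
        if rho[i] > rho_threshold and delta[i] > delta_threshold:
            labels[i] = nxt
            nxt += 1
        else:
            labels[i] = labels[parent[i]] if parent[i] >= 0 else 0
    return np.array(labels)


def test_assignment_matches_bruteforce_oracle(rng):
    X, _ = _blobs(rng, n=25, sep=8.0)
    from scipy.spatial.distance import pdist
    d_c = np.percentile(pdist(X), 2.0)
    params = stcluster.ClusterParams(rho_threshold=2, delta_threshold=4)
    labels, _ = stcluster.density_peak_cluster(X, params)
    oracle = brute_force_density_peak(X, 2, 4, d_c)
    assert adjusted_rand_score(labels, oracle) == 1.0


def test_point_order_invariance(rng):
    X, _ = _blobs(rng, n=40)
    labels, _ = stcluster.density_peak_cluster(X)
    perm = rng.permutation(len(X))
    labels_p, _ = stcluster.density_peak_cluster(X[perm])
    assert adjusted_rand_score(labels[perm], labels_p) == 1.0


# ------------------------------------------ differential expression

def test_z_matches_textbook_rank_sum():
    """Two groups of 5, complete separation: z from the closed form."""
    values = np.array([[1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10]])
    labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
    df = pd.DataFrame(values, index=["g"])
    de = stcluster.differential_expression(df, labels, z_cut=2.58)
    # R1 (group 1) = 15, mu = 27.5, sigma = sqrt(25 * 11 / 12)
    z_expected = (15 - 27.5) / math.sqrt(25 * 11 / 12)
    z0 = de.loc[de["cluster"] == 1, "z"].iloc[0]
    assert z0 == pytest.approx(z_expected, abs=1e-12)


def test_exclusive_gene_flagged_up(rng):
    X = np.zeros((3, 30))
    labels = np.repeat([0, 1, 2], 10)
    X[0, labels == 0] = 5.0  # expressed only in cluster 0
    X[1] = rng.normal(2, 0.1, 30)
    X[2] = rng.normal(1, 0.1, 30)
    de = stcluster.differential_expression(pd.DataFrame(X, index=list("abc")), labels)
    row = de[(de["gene"] == "a") & (de["cluster"] == 0)].iloc[0]
    assert row["significant"] and row["direction"] == "up"


def test_z_antisymmetric_between_two_clusters(rng):
    X = rng.normal(0, 1, (20, 40))
    labels = np.repeat([0, 1], 20)
    de = stcluster.differential_expression(pd.DataFrame(X), labels)
    z0 = de[de["cluster"] == 0].set_index("gene")["z"]
    z1 = de[de["cluster"] == 1].set_index("gene")["z"]
    assert np.allclose(z0, -z1.loc[z0.index], atol=1e-12)


def test_small_clusters_skipped(rng):
    X = rng.normal(0, 1, (5, 23))
    labels = np.array([0] * 20 + [1] * 2 + [2] * 1)
    de = stcluster.differential_expression(pd.DataFrame(X), labels)
    assert set(de["cluster"]) == {0}


def test_null_permutation_false_positive_rate(rng):
    fracs = []
    for _ in range(5):
        X = rng.poisson(3.0, (100, 100)).astype(float)
        labels = rng.permutation(np.repeat([0, 1], 50))
        de = stcluster.differential_expression(
            pd.DataFrame(np.log2(X + 1)), labels, z_cut=2.58)
        fracs.append(de[de["cluster"] == 0]["significant"].mean())
    assert np.mean(fracs) <= 0.04


def test_twocomp_engine_detects_expressed_shift(rng):
    X = np.zeros((1, 60))
    labels = np.repeat([0, 1], 30)
    X[0] = np.where(rng.random(60) < 0.3, 0.0, rng.normal(2, 0.3, 60))
    X[0, labels == 1] += np.where(X[0, labels == 1] > 0, 3.0, 0.0)
    de = stcluster.differential_expression(pd.DataFrame(X, index=["g"]), labels,
                                           engine="twocomp")
    assert de[de["cluster"] == 1].iloc[0]["significant"]


# -------------------------------------------------------- enrichment

def test_hypergeometric_matches_exhaustive_enumeration():
    """P(X >= k) for universe 10, list 4, set 5 by literal enumeration."""
    universe = list(range(10))
    geneset = set(range(5))
    observed_list = [0, 1, 2, 9]  # overlap 3
    sets = SignatureSet()
    sets.add("S", list(geneset))
    table = stcluster.hypergeometric_enrichment(observed_list, sets, universe)
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, 4):
        total += 1
        if len(set(draw) & geneset) >= 3:
            hits += 1
    assert table.loc[0, "p"] == pytest.approx(hits / total, abs=1e-12)


def test_disjoint_set_skipped_and_zero_overlap_p_one():
    sets = SignatureSet()
    sets.add("disjoint", ["x", "y"])
    sets.add("inside", ["g5", "g6"])
    universe = [f"g{i}" for i in range(10)]
    table = stcluster.hypergeometric_enrichment(["g0", "g1"], sets, universe)
    assert list(table["set"]) == ["inside"]
    assert table.loc[0, "p"] == pytest.approx(1.0)  # overlap 0 -> upper tail at 0


def _step_up_bh(p):
    """Directly coded Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_ix in range(m - 1, -1, -1):
        i = order[rank_ix]
        prev = min(prev, p[i] * m / (rank_ix + 1))
        adj[i] = prev
    return adj


def test_enrichment_fdr_matches_direct_step_up(rng):
    """The table's FDR column reproduces the step-up rule on its own P's."""
    universe = [f"g{i}" for i in range(60)]
    for _ in range(20):
        sets = SignatureSet()
        for k in range(12):
            members = rng.choice(universe, size=rng.integers(3, 20), replace=False)
            sets.add(f"S{k}", list(members))
        gene_list = list(rng.choice(universe, size=15, replace=False))
        table = stcluster.hypergeometric_enrichment(gene_list, sets, universe)
        assert np.allclose(table["fdr"], _step_up_bh(table["p"]), atol=1e-12)
        # monotone in raw P
        assert (np.diff(table["fdr"].to_numpy()) >= -1e-12).all()


def test_empty_universe_raises():
    with pytest.raises(ValueError):
        stcluster.hypergeometric_enrichment([], SignatureSet(), [])


def test_z_critical_value():
    assert round(stcluster.z_critical(0.01), 2) == 2.58
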