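"""Correlation ranking, pseudotime binning, HMM binarization, overlaps."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from stemtrack import dynamics as stdyn
from stemtrack import trajectory as sttraj


# ---------------------------------------------------------- correlation

def test_spearman_matches_scipy_with_ties(rng):
    X = rng.integers(0, 5, (20, 30)).astype(float)  # heavy ties
    pt = rng.uniform(0, 1, 30)
    mine = stdyn.spearman_vs_pseudotime(pd.DataFrame(X), pt)
    for g in range(20):
        ref = scipy.stats.spearmanr(X[g], pt).statistic
        if np.isnan(ref):
            assert np.isnan(mine.iloc[g])
        else:
            assert mine.iloc[g] == pytest.approx(ref, abs=1e-12)


def test_monotone_gene_has_rho_one():
    pt = np.linspace(0, 1, 25)
    df = pd.DataFrame(np.vstack([pt ** 3, np.full(25, 2.0)]), index=["mono", "const"])
    rho = stdyn.spearman_vs_pseudotime(df, pt)
    assert rho["mono"] == pytest.approx(1.0)
    assert np.isnan(rho["const"])


def _path(cells, pt):
    return sttraj.PathSpec(states=["S1"], cells=list(cells),
                           pseudotime=pd.Series(pt, index=cells))


def test_top_lists_disjoint_and_cutoffs_reported(rng):
    cells = [f"c{j}" for j in range(40)]
    pt = np.sort(rng.uniform(0, 1, 40))
    X = rng.normal(0, 1, (200, 40))
    X[:20] += 3 * pt
    X[20:40] -= 3 * pt
    expr = pd.DataFrame(X, index=[f"g{i}" for i in range(200)], columns=cells)
    corr = stdyn.correlate_with_pseudotime(expr, _path(cells, pt), top_n=1000)
    assert corr.top_n == 50  # capped at a quarter of usable genes
    assert not set(corr.top("pos")) & set(corr.top("neg"))
    assert corr.pos_cutoff > 0 > corr.neg_cutoff


def test_planted_trend_genes_dominate_top_list(small_dataset):
    from stemtrack import preprocess as stpre

    _c, tpm, _gm, truth = small_dataset
    cells_meta = truth.cells.set_index("cell")
    tumor = cells_meta.index[cells_meta["is_tumor"]]
    expr = np.log2(tpm.data.loc[:, tumor] + 1.0)
    expr = stpre.regress_patient_effect(expr, cells_meta.loc[tumor, "patient"])
    pt = cells_meta.loc[tumor, "latent_time"].to_numpy()
    order = np.argsort(pt)
    corr = stdyn.correlate_with_pseudotime(
        expr, _path(tumor[order], pt[order]), top_n=1000)
    top_pos = set(corr.top("pos"))
    planted = set(truth.signatures["INVASIVE"])
    assert len(top_pos & planted) / len(planted) >= 0.8


# -------------------------------------------------------------- binning

def test_bin_means_hand_example():
    pt = np.arange(40.0)
    means, empty = stdyn.bin_pseudotime(pt.copy(), pt, n_bins=20)
    assert np.allclose(means, np.arange(0.5, 39, 2.0))
    assert not empty.any()


def test_single_bin_is_global_mean(rng):
    v = rng.normal(0, 1, 30)
    means, _ = stdyn.bin_pseudotime(v, rng.uniform(0, 1, 30), n_bins=1)
    assert means[0] == pytest.approx(v.mean())


def test_bin_means_permutation_invariant(rng):
    v = rng.normal(0, 1, 50)
    pt = rng.uniform(0, 1, 50)
    a, _ = stdyn.bin_pseudotime(v, pt, n_bins=10)
    perm = rng.permutation(50)
    b, _ = stdyn.bin_pseudotime(v[perm], pt[perm], n_bins=10)
    assert np.allclose(a, b)


def test_empty_bins_interpolated_and_sparse_raises():
    pt = np.array([0.0, 0.05, 0.9, 1.0])
    v = np.array([1.0, 1.0, 3.0, 3.0])
    means, empty = stdyn.bin_pseudotime(v, pt, n_bins=4, max_empty_fraction=0.6)
    assert empty.tolist() == [False, True, True, False]
    assert np.all(np.diff(means) >= 0)  # linear interpolation between 1 and 3
    with pytest.raises(ValueError, match="sparse"):
        stdyn.bin_pseudotime(v, pt, n_bins=12)


# ------------------------------------------------------------------ HMM

def test_noiseless_step_decoded_exactly():
    y = np.array([0.0] * 5 + [2.0] * 5)
    fit = stdyn.fit_binarize(y, seed=0)
    assert fit.states.tolist() == [0] * 5 + [1] * 5
    assert fit.switch_bins == [5]
    assert fit.means[1] > fit.means[0]
    assert np.allclose(fit.transmat.sum(axis=1), 1.0)


def test_em_loglik_nondecreasing(rng):
    for _ in range(10):
        y = rng.normal(0, 1, 20) + np.r_[np.zeros(10), np.full(10, 1.5)]
        fit = stdyn.fit_binarize(y, seed=1)
        gains = np.diff(fit.loglik_history)
        assert (gains >= -1e-8).all()
        assert fit.loglik >= fit.loglik_history[0]


def brute_force_viterbi(y, means, sds, A, pi):
    best, best_lp = None, -np.inf
    for cand in itertools.product((0, 1), repeat=len(y)):
        lp = math.log(pi[cand[0]]) + scipy.stats.norm.logpdf(y[0], means[cand[0]], sds[cand[0]])
        for t in range(1, len(y)):
            lp += math.log(A[cand[t - 1], cand[t]])
            lp += scipy.stats.norm.logpdf(y[t], means[cand[t]], sds[cand[t]])
        if lp > best_lp:
            best, best_lp = cand, lp
    return np.array(best)


def test_viterbi_matches_bruteforce(rng):
    for _ in range(30):
        y = rng.normal(0, 1.5, 5)
        means = np.sort(rng.normal(0, 2, 2))
        sds = rng.uniform(0.3, 2.0, 2)
        A = rng.dirichlet([3, 1], 2)
        pi = rng.dirichlet([1, 1])
        assert np.array_equal(stdyn.viterbi(y, means, sds, A, pi),
                              brute_force_viterbi(y, means, sds, A, pi))


def test_viterbi_matches_hmmlearn(rng):
    hmm = pytest.importorskip("hmmlearn.hmm")
    for _ in range(5):
        y = rng.normal(0, 1, 12)
        means = np.array([-1.0, 1.5])
        sds = np.array([0.8, 1.2])
        A = np.array([[0.85, 0.15], [0.1, 0.9]])
        pi = np.array([0.6, 0.4])
        model = hmm.GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        model.startprob_ = pi
        model.transmat_ = A
        model.means_ = means[:, None]
        model.covars_ = (sds ** 2)[:, None]
        ref = model.predict(y[:, None])
        assert np.array_equal(stdyn.viterbi(y, means, sds, A, pi), ref)


def test_switch_recovery_cell_level(rng):
    """Planted per-cell steps, binned then decoded: switch within one bin."""
    n_cells, n_bins = 300, 20
    pt = np.linspace(0, 1, n_cells)
    hits = 0
    for _ in range(20):
        true = int(rng.integers(3, 17))
        vals = np.where(pt >= true / n_bins, 2.0, 0.0) + rng.normal(0, 1, n_cells)
        y, _ = stdyn.bin_pseudotime(vals, pt, n_bins=n_bins)
        fit = stdyn.fit_binarize(y, seed=0)
        if len(fit.switch_bins) == 1 and abs(fit.switch_bins[0] - true) <= 1:
            hits += 1
    assert hits >= 18


def test_binarize_genes_matrix(rng):
    mat = pd.DataFrame(
        np.vstack([np.r_[np.zeros(10), np.ones(10) * 3],
                   np.r_[np.ones(10) * 3, np.zeros(10)]]),
        index=["up", "down"])
    states, fits = stdyn.binarize_genes(mat, seed=0)
    assert states.loc["up"].tolist() == [0] * 10 + [1] * 10
    assert states.loc["down"].tolist() == [1] * 10 + [0] * 10
    assert fits["up"].switch_bins == [10]


def test_too_few_bins_raises():
    with pytest.raises(ValueError):
        stdyn.fit_binarize([1.0, 2.0, 3.0], seed=0)


# -------------------------------------------------- catalogs, overlap

def test_catalog_filter_identity_disjoint_and_oracle(rng):
    table = pd.DataFrame({"gene": [f"g{i}" for i in range(30)],
                          "rho": rng.uniform(-1, 1, 30),
                          "list": ["pos"] * 10 + ["neg"] * 10 + ["none"] * 10})
    everything = stdyn.filter_by_catalog(table, table["gene"])
    pd.testing.assert_frame_equal(everything, table)
    assert stdyn.filter_by_catalog(table, ["zzz"]).empty
    catalog = {f"g{i}" for i in range(0, 30, 3)}
    sub = stdyn.filter_by_catalog(table, catalog)
    assert set(sub["gene"]) == catalog & set(table["gene"])
    assert list(sub.index) == sorted(sub.index)  # original order retained


def test_overlap_zero_is_p_one():
    res = stdyn.overlap_significance(["a", "b"], ["c", "d"], universe_size=20)
    assert res.p == pytest.approx(1.0)
    assert res.intersection == 0


def test_full_overlap_exact_probability():
    genes = [f"g{i}" for i in range(5)]
    res = stdyn.overlap_significance(genes, genes, universe_size=20)
    assert res.p == pytest.approx(1 / math.comb(20, 5), abs=1e-15)


def test_overlap_p_monotone_in_intersection():
    a = [f"a{i}" for i in range(6)]
    ps = []
    for k in range(7):
        b = a[:k] + [f"b{i}" for i in range(6 - k)]
        ps.append(stdyn.overlap_significance(a, b, universe_size=40).p)
    assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))


def test_overlap_universe_too_small_raises():
    with pytest.raises(ValueError):
        stdyn.overlap_significance(list("abcdef"), list("ab"), universe_size=3)


def test_cv_report_contrasts_groups(rng):
    X = np.vstack([rng.normal(5, 2.0, (20, 40)), rng.normal(5, 0.2, (20, 40))])
    df = pd.DataFrame(X, index=[f"g{i}" for i in range(40)])
    flags = pd.Series([True] * 20 + [False] * 20, index=df.index)
    rep = stdyn.expression_cv_report(df, flags)
    assert rep["cv_group"] > rep["cv_rest"]
    assert 0 <= rep["p"] <= 1
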