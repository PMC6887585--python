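"""QC, census conversion, scaling factors, RUV and patient regression."""

import numpy as np
import pandas as pd
import pytest

from stemtrack import preprocess as stpre
from stemtrack import synthetic as stsynth
from stemtrack._types import ExpressionMatrix


def _expr(matrix, unit="counts", genes=None, cells=None):
    matrix = np.asarray(matrix, float)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    cells = cells or [f"c{j}" for j in range(matrix.shape[1])]
    return ExpressionMatrix(pd.DataFrame(matrix, index=genes, columns=cells), unit)


# ----------------------------------------------------------------- QC

def test_qc_keeps_exactly_the_hand_counted_cells():
    detected = [10, 3000, 2999, 5000, 0]
    X = np.zeros((5000, 5))
    for j, d in enumerate(detected):
        X[:d, j] = 1.0
    counts = _expr(X)
    kept, report = stpre.qc_filter_cells(
        counts, stpre.QcParams(min_detected_genes=3000, min_total_counts=0))
    assert kept == ["c1", "c3"]
    assert report.loc["c4", "reason"] == "detected genes"
    assert not report.loc["c4", "kept"]


def test_qc_zero_thresholds_keep_everything(small_dataset):
    counts = small_dataset[0]
    kept, _ = stpre.qc_filter_cells(
        counts, stpre.QcParams(min_detected_genes=0, min_total_counts=0))
    assert kept == list(counts.cells)


def test_qc_raises_when_all_cells_fail(small_dataset):
    counts = small_dataset[0]
    with pytest.raises(ValueError):
        stpre.qc_filter_cells(counts, stpre.QcParams(min_detected_genes=10**9))


def test_gene_filter_intersection_rule():
    # gene zero in 96% of patient A cells but well expressed in patient B -> kept
    X = np.ones((2, 50))
    X[0, :24] = 0.0  # gene 0: zero in 96% of A (24/25), expressed in B
    X[0, 24] = 0.0
    X[0, 25:] = 5.0
    X[1, :] = 0.0    # gene 1: zero everywhere -> removed
    counts = _expr(X)
    patients = pd.Series(["A"] * 25 + ["B"] * 25, index=counts.cells)
    kept = stpre.filter_unexpressed_genes(counts, patients, fraction=0.95)
    assert kept == ["g0"]


def test_gene_filter_matches_two_loop_oracle(rng):
    X = (rng.random((60, 40)) < 0.3) * rng.integers(1, 9, (60, 40))
    counts = _expr(X)
    patients = pd.Series(["A"] * 15 + ["B"] * 15 + ["C"] * 10, index=counts.cells)
    kept = stpre.filter_unexpressed_genes(counts, patients, fraction=0.9)

    removed_oracle = []
    for g in range(60):
        drop = True
        for pat in ("A", "B", "C"):
            cols = patients[patients == pat].index
            frac0 = (counts.data.loc[f"g{g}", cols] == 0).mean()
            if frac0 < 0.9:
                drop = False
        if drop:
            removed_oracle.append(f"g{g}")
    assert set(kept) == set(counts.genes) - set(removed_oracle)


# ------------------------------------------------------------- census

def _symmetric_cell():
    log10_vals = np.array([0.2, 0.4, 0.6, 0.8, 0.95, 1.0, 1.05, 1.2, 1.4, 1.6, 1.8])
    return 10.0 ** log10_vals


def test_census_mode_scaling_matches_density_oracle():
    tpm_vals = _symmetric_cell()
    X = np.zeros((len(tpm_vals) + 3, 1))
    X[:len(tpm_vals), 0] = tpm_vals
    tpm = _expr(X, unit="tpm")
    census, flagged = stpre.census_counts(tpm)
    assert not flagged
    ratio = tpm_vals / census.data.iloc[:len(tpm_vals), 0].to_numpy()
    # detected values are symmetric about log10 = 1, so t* = 10
    assert np.allclose(ratio, 10.0, rtol=0.02)


def test_census_scale_invariance():
    tpm_vals = _symmetric_cell()
    X = np.zeros((len(tpm_vals), 2))
    X[:, 0] = tpm_vals
    X[:, 1] = tpm_vals * 7.3
    tpm = _expr(X, unit="tpm")
    census, _ = stpre.census_counts(tpm)
    assert np.allclose(census.data.iloc[:, 0], census.data.iloc[:, 1], rtol=1e-9)


def test_census_preserves_rank_order(small_dataset):
    _counts, tpm, *_ = small_dataset
    census, flagged = stpre.census_counts(tpm)
    cell = [c for c in tpm.cells if c not in flagged][0]
    a = tpm.data[cell].rank()
    b = census.data[cell].rank()
    assert (a == b).all()


def test_census_flags_sparse_cells():
    X = np.zeros((30, 1))
    X[:3, 0] = [10.0, 20.0, 30.0]
    census, flagged = stpre.census_counts(_expr(X, unit="tpm"))
    assert flagged == ["c0"]


# ----------------------------------------------------- scaling factors

def test_library_factors_proportional_cells():
    base = np.array([[2.0, 4.0], [6.0, 12.0], [1.0, 2.0]])
    counts = _expr(base)
    factors, _dropped = stpre.scaling_factors(counts)
    assert factors["c1"] / factors["c0"] == pytest.approx(2.0)
    norm = stpre.normalize(counts, factors)
    assert np.allclose(norm.log_expr["c0"], norm.log_expr["c1"])


def test_factors_geometric_mean_one(small_dataset):
    counts = small_dataset[0]
    factors, _ = stpre.scaling_factors(counts)
    assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-9)


def test_pooling_recovers_planted_depth_factors(rng):
    theta = rng.uniform(0.4, 2.5, 20)
    lam = rng.uniform(50, 500, 300)
    X = np.outer(lam, theta)
    counts = _expr(X)
    factors, _ = stpre.scaling_factors(counts, method="pooling")
    target = theta / np.exp(np.mean(np.log(theta)))
    rel_err = np.abs(factors.to_numpy() / target - 1.0)
    assert rel_err.max() <= 0.05


def test_zero_depth_cell_dropped():
    X = np.array([[1.0, 0.0], [2.0, 0.0]])
    factors, dropped = stpre.scaling_factors(_expr(X))
    assert "c1" not in factors.index
    assert "zero depth" in dropped["reason"].tolist()


# --------------------------------------------------------------- RUV

def _planted_factor_data(rng, n_genes=60, n_cells=40, n_hk=10):
    base = rng.normal(5, 1, (n_genes, n_cells))
    f = rng.normal(0, 1, n_cells)
    gamma = rng.uniform(0.5, 1.5, n_genes)
    X = base * 0.1 + np.outer(gamma, f)
    genes = [f"g{i}" for i in range(n_genes)]
    df = pd.DataFrame(X, index=genes, columns=[f"c{j}" for j in range(n_cells)])
    return df, genes[:n_hk], f


def test_ruv_removes_planted_factor(rng):
    df, hk, f = _planted_factor_data(rng)
    cleaned = stpre.remove_unwanted_variation(df, hk, k=1).log_expr
    for g in hk:
        corr = np.corrcoef(cleaned.loc[g], f)[0, 1]
        assert abs(corr) <= 0.1


def test_ruv_loadings_orthonormal(rng):
    df, hk, _f = _planted_factor_data(rng)
    res = stpre.remove_unwanted_variation(df, hk, k=2)
    gram = res.loadings.T @ res.loadings
    assert np.allclose(gram, np.eye(2), atol=1e-9)


def test_ruv_k_zero_is_identity(rng):
    df, hk, _f = _planted_factor_data(rng)
    out = stpre.remove_unwanted_variation(df, hk, k=0).log_expr
    pd.testing.assert_frame_equal(out, df)


def test_ruv_leaves_orthogonal_genes_unchanged(rng):
    """A gene orthogonal to the housekeeping factor keeps its values."""
    n_cells = 32
    f = np.zeros(n_cells)
    f[: n_cells // 2] = 1.0
    f -= f.mean()
    ortho = np.tile([1.0, -1.0], n_cells // 2)  # orthogonal to the step factor
    assert abs(np.dot(ortho, f)) < 1e-12
    rows = {f"hk{i}": 5 + (1 + 0.1 * i) * f for i in range(6)}
    rows["probe"] = 3 + ortho
    df = pd.DataFrame(rows).T
    df.columns = [f"c{j}" for j in range(n_cells)]
    cleaned = stpre.remove_unwanted_variation(df, [f"hk{i}" for i in range(6)], k=1)
    assert np.allclose(cleaned.log_expr.loc["probe"], df.loc["probe"], atol=1e-6)


def test_ruv_requires_enough_cells(rng):
    df, hk, _f = _planted_factor_data(rng, n_cells=5)
    with pytest.raises(ValueError):
        stpre.remove_unwanted_variation(df, hk, k=5)


# ------------------------------------------------- patient regression

def test_patient_regression_equalizes_means(rng):
    X = rng.normal(0, 1, (30, 40)) + np.repeat([0.0, 2.0], 20)[None, :]
    df = pd.DataFrame(X, index=[f"g{i}" for i in range(30)],
                      columns=[f"c{j}" for j in range(40)])
    patients = pd.Series(["A"] * 20 + ["B"] * 20, index=df.columns)
    adj = stpre.regress_patient_effect(df, patients)
    grand = adj.mean(axis=1)
    for pat in ("A", "B"):
        pmean = adj.loc[:, patients[patients == pat].index].mean(axis=1)
        assert np.abs(pmean - grand).max() <= 1e-9


def test_single_patient_is_identity(rng):
    df = pd.DataFrame(rng.normal(0, 1, (10, 8)))
    out = stpre.regress_patient_effect(df, pd.Series(["A"] * 8, index=df.columns))
    pd.testing.assert_frame_equal(out, df)


def test_patient_variance_drops_below_one_percent():
    cfg = stsynth.SynthConfig(
        n_patients=3, cells_per_patient=60, n_genes=300, n_chromosomes=3,
        normal_cell_fraction=0.0, cnv_segments=(), patient_effect_sd=1.0,
        stem_set_size=10, invasive_set_size=10, g1s_set_size=5, g2m_set_size=5,
        alt_branch_set_size=5, housekeeping_count=10, cnv_window_hint=10, seed=17,
    )
    _c, tpm, _gm, truth = stsynth.generate_dataset(cfg)
    log_expr = np.log2(tpm.data + 1.0)
    patients = truth.cells.set_index("cell")["patient"]

    def eta_squared(df):
        grand = df.to_numpy().mean(axis=1, keepdims=True)
        ss_tot = ((df.to_numpy() - grand) ** 2).sum()
        ss_between = 0.0
        for pat in patients.unique():
            cols = patients[patients == pat].index
            sub = df.loc[:, cols].to_numpy()
            ss_between += sub.shape[1] * ((sub.mean(axis=1, keepdims=True) - grand) ** 2).sum()
        return ss_between / ss_tot

    before = eta_squared(log_expr)
    after = eta_squared(stpre.regress_patient_effect(log_expr, patients))
    assert before > 0.05
    assert after < 0.01


def test_covariate_regression_removes_cell_covariate(rng):
    cov = rng.normal(0, 1, 40)
    X = rng.normal(0, 0.1, (20, 40)) + np.outer(rng.uniform(1, 2, 20), cov)
    df = pd.DataFrame(X, columns=[f"c{j}" for j in range(40)])
    cleaned = stpre.regress_covariates(df, cov)
    corrs = [abs(np.corrcoef(cleaned.iloc[g], cov)[0, 1]) for g in range(20)]
    assert max(corrs) < 0.05
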