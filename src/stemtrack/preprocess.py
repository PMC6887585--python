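"""Quality filtering, normalization and nuisance-variation removal.

The preprocessing chain runs, in order: cell quality filtering (detected
genes and a count-depth proxy), a per-patient non-expression gene filter
(removing only genes silent in at least 95% of every patient's cells),
a Census-style TPM-to-relative-count conversion, cell scaling-factor
normalization, SVD-based removal of unwanted variation estimated from
housekeeping genes, and — at clustering time — least-squares regression of
per-patient offsets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._types import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class QcParams:
    """Cell/gene quality thresholds.

    ``min_detected_genes`` and ``min_total_counts`` generalize read-level
    quality filters to what a matrix can support; both scale with the
    dataset.  ``min_transcriptomic_diversity`` is the minimum detected-gene
    fraction relative to the cohort median below which a cell is dropped
    during scaling-factor estimation.
    """

    min_detected_genes: int = 3000
    min_total_counts: float = 2e5
    nonexpressed_cell_fraction: float = 0.95
    min_transcriptomic_diversity: float = 0.25

    def validate(self) -> None:
        if not 0.0 <= self.nonexpressed_cell_fraction <= 1.0:
            raise ValueError("nonexpressed_cell_fraction must lie in [0, 1]")
        if not 0.0 <= self.min_transcriptomic_diversity <= 1.0:
            raise ValueError("min_transcriptomic_diversity must lie in [0, 1]")


@dataclass
class NormalizedMatrix:
    """Log2 expression after normalization, plus provenance.

    ``factors`` are the per-cell scaling factors used; ``loadings`` holds
    the orthonormal cell-side factors removed by RUV (empty before RUV).
    """

    log_expr: pd.DataFrame
    factors: pd.Series | None = None
    loadings: np.ndarray | None = None
    dropped_cells: pd.DataFrame = field(default_factory=pd.DataFrame)


# ----------------------------------------------------------------- QC

def qc_filter_cells(counts: ExpressionMatrix, params: QcParams | None = None):
    """Keep cells passing both the detected-gene and total-count filters.

    Returns ``(kept_cells, report)`` where the report lists, per cell, the
    detected-gene count, the total counts and the removal reasons.
    """
    params = params or QcParams()
    params.validate()
    X = counts.data
    detected = (X > 0).sum(axis=0)
    totals = X.sum(axis=0)
    ok_genes = detected >= params.min_detected_genes
    ok_depth = totals >= params.min_total_counts
    keep = ok_genes & ok_depth
    reasons = []
    for g, d in zip(ok_genes, ok_depth):
        r = []
        if not g:
            r.append("detected genes")
        if not d:
            r.append("total counts")
        reasons.append(";".join(r))
    report = pd.DataFrame(
        {"detected_genes": detected, "total_counts": totals, "kept": keep, "reason": reasons},
        index=X.columns,
    )
    if not keep.any():
        raise ValueError("QC removed every cell; thresholds too strict for this matrix")
    return list(X.columns[keep]), report


def filter_unexpressed_genes(counts: ExpressionMatrix, patient_labels: pd.Series,
                             fraction: float = 0.95) -> list:
    """Per-patient non-expression filter (intersection rule).

    A gene is removed only if, in *every* patient, it is zero in at least
    ``fraction`` of that patient's cells; the survivors are returned.
    """
    X = counts.data
    labels = pd.Series(patient_labels).reindex(X.columns)
    if labels.isna().any():
        raise ValueError("patient labels must cover every cell")
    remove = np.ones(X.shape[0], dtype=bool)
    for _pat, cols in labels.groupby(labels).groups.items():
        frac_zero = (X.loc[:, cols] == 0).mean(axis=1).to_numpy()
        remove &= frac_zero >= fraction
    return list(X.index[~remove])


# ------------------------------------------------------------- Census

def census_counts(tpm: ExpressionMatrix, detection_min_tpm: float = 0.1,
                  min_detected: int = 10, grid_size: int = 512):
    """Census-style conversion of TPM to relative counts.

    Per cell, the mode ``t*`` of the kernel density of log10 TPM over
    detected genes (TPM >= ``detection_min_tpm``) estimates the TPM value
    of a single transcript; relative counts are ``TPM / t*``.  Cells with
    fewer than ``min_detected`` detected genes get no factor and are
    flagged.  Returns ``(ExpressionMatrix[census], flagged_cells)``.
    """
    if tpm.unit != "tpm":
        raise ValueError(f"census conversion expects TPM, got {tpm.unit!r}")
    X = tpm.data.to_numpy(float)
    out = np.empty_like(X)
    flagged = []
    for j, cell in enumerate(tpm.cells):
        vals = X[:, j]
        det = vals[vals >= detection_min_tpm]
        if det.size < min_detected:
            flagged.append(cell)
            out[:, j] = np.nan
            continue
        logv = np.log10(det)
        if np.ptp(logv) < 1e-12:
            t_star = 10.0 ** logv[0]
        else:
            kde = gaussian_kde(logv)
            grid = np.linspace(logv.min(), logv.max(), grid_size)
            t_star = 10.0 ** grid[np.argmax(kde(grid))]
        out[:, j] = vals / t_star
    result = ExpressionMatrix(pd.DataFrame(out, index=tpm.genes, columns=tpm.cells), "census")
    return result, flagged


# ------------------------------------------------- scaling factors

def scaling_factors(counts: ExpressionMatrix, method: str = "library",
                    params: QcParams | None = None, pool_size: int = 5):
    """Per-cell scaling factors, geometric mean anchored at 1.

    ``library``: total counts divided by their geometric mean.
    ``pooling``: rolling pools of cells (ordered by depth) give robust
    pool-level size estimates; per-cell factors are recovered by least
    squares from the pool sums (a deconvolution in the style of
    scran).  Cells whose factor cannot be estimated (zero depth, or
    transcriptomic diversity below threshold) are dropped and reported.

    Returns ``(factors, dropped_report)``.
    """
    params = params or QcParams()
    X = counts.data
    totals = X.sum(axis=0).to_numpy(float)
    detected = (X > 0).sum(axis=0).to_numpy(float)
    med_det = np.median(detected)

    drop_reason = {}
    for j, cell in enumerate(X.columns):
        if totals[j] <= 0:
            drop_reason[cell] = "zero depth"
        elif med_det > 0 and detected[j] < params.min_transcriptomic_diversity * med_det:
            drop_reason[cell] = "low transcriptomic diversity"
    keep = [c for c in X.columns if c not in drop_reason]
    if not keep:
        raise ValueError("no cell has an estimable scaling factor")
    Xk = X.loc[:, keep].to_numpy(float)
    n = len(keep)

    if method == "library":
        tot = Xk.sum(axis=0)
        raw = tot.copy()
    elif method == "pooling":
        order = np.argsort(Xk.sum(axis=0), kind="mergesort")
        ref = Xk.mean(axis=1)
        ok = ref > 0
        # several pool sizes around pool_size: a single ring size gives a
        # circulant design with zero eigenvalues (underdetermined system)
        sizes = sorted({max(2, pool_size - 1), min(pool_size, n),
                        min(pool_size + 1, n)})
        rows, rhs = [], []
        for p in sizes:
            for i in range(n):
                members = order[(np.arange(i, i + p)) % n]
                pool = Xk[:, members].sum(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    rhs.append(np.median(pool[ok] / ref[ok]))
                row = np.zeros(n)
                row[members] = 1.0
                rows.append(row)
        raw, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
        raw = np.asarray(raw)
    else:
        raise ValueError(f"unknown scaling method {method!r}")

    bad = raw <= 0
    for j in np.flatnonzero(bad):
        drop_reason[keep[j]] = "non-positive factor"
    keep = [c for j, c in enumerate(keep) if not bad[j]]
    raw = raw[~bad]
    if raw.size == 0:
        raise ValueError("no cell has a positive scaling factor")
    factors = pd.Series(raw / np.exp(np.mean(np.log(raw))), index=keep, name="factor")
    dropped = pd.DataFrame(
        {"cell": list(drop_reason), "reason": list(drop_reason.values())}
    )
    return factors, dropped


def normalize(counts: ExpressionMatrix, factors: pd.Series) -> NormalizedMatrix:
    """Divide each cell by its scaling factor and return log2(x + 1)."""
    cells = [c for c in counts.cells if c in factors.index]
    X = counts.data.loc[:, cells].to_numpy(float) / factors.loc[cells].to_numpy()
    log_expr = pd.DataFrame(np.log2(X + 1.0), index=counts.genes, columns=cells)
    dropped = pd.DataFrame({"cell": [c for c in counts.cells if c not in factors.index]})
    return NormalizedMatrix(log_expr=log_expr, factors=factors.loc[cells], dropped_cells=dropped)


# ------------------------------------------------------------ RUV

def remove_unwanted_variation(log_expr: pd.DataFrame, housekeeping_genes,
                              k: int = 1) -> NormalizedMatrix:
    """Regress out cell-side factors estimated from housekeeping genes.

    The top ``k`` right singular vectors of the row-centered housekeeping
    submatrix define orthonormal cell factors; every gene is regressed on
    them and replaced by its residual plus its mean.  ``k = 0`` is the
    identity.
    """
    hk = [g for g in housekeeping_genes if g in log_expr.index]
    if len(hk) < 5:
        raise ValueError(f"need >= 5 housekeeping genes present, found {len(hk)}")
    n_cells = log_expr.shape[1]
    if k >= n_cells:
        raise ValueError("k must be smaller than the number of cells")
    if k == 0:
        return NormalizedMatrix(log_expr=log_expr.copy(), loadings=np.zeros((n_cells, 0)))

    H = log_expr.loc[hk].to_numpy(float)
    Hc = H - H.mean(axis=1, keepdims=True)
    _u, _s, vt = np.linalg.svd(Hc, full_matrices=False)
    W = vt[:k].T  # cells x k, orthonormal columns

    X = log_expr.to_numpy(float)
    means = X.mean(axis=1, keepdims=True)
    Xc = X - means
    beta = Xc @ W
    resid = Xc - beta @ W.T + means
    return NormalizedMatrix(
        log_expr=pd.DataFrame(resid, index=log_expr.index, columns=log_expr.columns),
        loadings=W,
    )


# ----------------------------------------------- covariate regression

def regress_covariates(log_expr: pd.DataFrame, covariates) -> pd.DataFrame:
    """Remove per-cell covariates (e.g. cell-cycle scores) from every gene.

    ``covariates`` is a cells x k array-like (or DataFrame/Series aligned
    to the cells).  Each gene is regressed on the covariates plus an
    intercept by least squares and replaced by intercept + residual, the
    usual way cell-cycle activity is removed before trajectory inference.
    """
    C = np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != log_expr.shape[1]:
        raise ValueError("covariates must have one row per cell")
    X = log_expr.to_numpy(float)
    design = np.column_stack([np.ones(C.shape[0]), C])
    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    cleaned = X.T - design[:, 1:] @ beta[1:]
    return pd.DataFrame(cleaned.T, index=log_expr.index, columns=log_expr.columns)


# ----------------------------------------------- patient regression

def regress_patient_effect(log_expr: pd.DataFrame, patient_labels: pd.Series) -> pd.DataFrame:
    """Remove per-patient, per-gene offsets by least squares.

    Fitting expression on patient indicators per gene and subtracting the
    fitted offsets equalizes the per-patient means; the grand mean is
    re-added.  A single patient leaves the matrix unchanged.
    """
    labels = pd.Series(patient_labels).reindex(log_expr.columns)
    if labels.isna().any():
        raise ValueError("patient labels must cover every cell")
    if labels.nunique() < 2:
        return log_expr.copy()
    sizes = labels.value_counts()
    for pat, sz in sizes.items():
        if sz == 1:
            warnings.warn(f"patient {pat} has a single cell; its offset is fit exactly",
                          stacklevel=2)
    X = log_expr.to_numpy(float)
    grand = X.mean(axis=1, keepdims=True)
    out = np.empty_like(X)
    for _pat, cols in labels.groupby(labels).groups.items():
        idx = log_expr.columns.get_indexer(cols)
        out[:, idx] = X[:, idx] - X[:, idx].mean(axis=1, keepdims=True) + grand
    return pd.DataFrame(out, index=log_expr.index, columns=log_expr.columns)
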