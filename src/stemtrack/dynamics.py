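"""Gene dynamics along a path: correlation ranking and HMM binarization.

Along an extracted root-to-terminal path, each gene is ranked by its
Spearman correlation with pseudotime; the top-N positively and negatively
correlated genes form the candidate driver lists (the achieved correlation
cutoffs are reported, not imposed).  Pseudotime is divided into bins, the
per-bin mean expression of a gene becomes the observation sequence of a
two-state Gaussian-emission hidden Markov model fit by Baum-Welch, and
Viterbi decoding yields the binary on/off profile with its switch bins.
Candidate lists can be restricted to catalogs (transcription factors,
lncRNAs) and compared across datasets with a hypergeometric overlap test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

log = logging.getLogger(__name__)


# ----------------------------------------------------- correlation

def spearman_vs_pseudotime(expr: pd.DataFrame, pseudotime: np.ndarray) -> pd.Series:
    """Spearman rho of every gene against pseudotime (average-rank ties).

    Constant genes get NaN (excluded downstream with a note).
    """
    X = expr.to_numpy(float)
    pt_rank = scipy.stats.rankdata(np.asarray(pseudotime, float))
    ranks = scipy.stats.rankdata(X, axis=1)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    pc = pt_rank - pt_rank.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (pc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, (rc @ pc) / denom, np.nan)
    return pd.Series(rho, index=expr.index, name="rho")


@dataclass
class CorrelationTable:
    """Per-gene correlation with pseudotime and top-list membership."""

    table: pd.DataFrame  # gene, rho, rank, list in {pos, neg, none}
    top_n: int
    pos_cutoff: float | None = None
    neg_cutoff: float | None = None

    def top(self, which: str) -> list:
        return self.table.loc[self.table["list"] == which, "gene"].tolist()


def correlate_with_pseudotime(log_expr: pd.DataFrame, path, top_n: int = 1000,
                              min_cells: int = 10) -> CorrelationTable:
    """Rank genes by Spearman correlation along a path.

    ``path`` is a PathSpec (or any object with ``cells`` and
    ``pseudotime``).  ``top_n`` is capped at a quarter of the usable genes
    so the two lists stay disjoint on small matrices.  The achieved rho
    cutoffs of the two lists are recorded.
    """
    cells = list(path.cells)
    if len(cells) < min_cells:
        raise ValueError(f"need >= {min_cells} cells on the path, got {len(cells)}")
    pt = path.pseudotime.loc[cells].to_numpy()
    sub = log_expr.loc[:, cells]
    rho = spearman_vs_pseudotime(sub, pt)
    n_const = int(rho.isna().sum())
    if n_const:
        log.info("%d constant genes excluded from correlation ranking", n_const)
    valid = rho.dropna()
    n_top = min(top_n, len(valid) // 4) if len(valid) < 4 * top_n else top_n
    order = valid.sort_values(ascending=False, kind="mergesort")
    pos = order.index[:n_top]
    neg = order.index[-n_top:][::-1]
    membership = pd.Series("none", index=rho.index, dtype=object)
    membership.loc[pos] = "pos"
    membership.loc[neg] = "neg"
    rank = valid.rank(ascending=False, method="first").reindex(rho.index)
    table = pd.DataFrame({"gene": rho.index, "rho": rho.to_numpy(),
                          "rank": rank.to_numpy(), "list": membership.to_numpy()})
    return CorrelationTable(
        table=table, top_n=n_top,
        pos_cutoff=float(valid.loc[pos].min()) if len(pos) else None,
        neg_cutoff=float(valid.loc[neg].max()) if len(neg) else None,
    )


# -------------------------------------------------------- binning

def bin_pseudotime(values, pseudotime, n_bins: int = 20, mode: str = "equal_width",
                   max_empty_fraction: float = 0.5):
    """Per-bin mean of ``values`` over a pseudotime axis.

    ``equal_width`` splits the pseudotime range evenly (``equal_count``
    puts the same number of cells in each bin).  Empty bins are filled by
    linear interpolation of neighboring bin means and flagged.  Returns
    ``(bin_means, empty_flags)``.
    """
    y = np.asarray(values, float)
    x = np.asarray(pseudotime, float)
    if y.shape[-1] != x.size:
        raise ValueError("values and pseudotime length mismatch")
    if mode == "equal_width":
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
    elif mode == "equal_count":
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    cnts = np.bincount(idx, minlength=n_bins)
    empty = cnts == 0
    if empty.mean() > max_empty_fraction:
        raise ValueError(f"path too sparse: {int(empty.sum())}/{n_bins} empty bins")
    means = np.full(n_bins, np.nan)
    means[~empty] = sums[~empty] / cnts[~empty]
    if empty.any():
        filled = np.flatnonzero(~empty)
        means[empty] = np.interp(np.flatnonzero(empty), filled, means[filled])
    return means, empty


def bin_matrix(expr: pd.DataFrame, pseudotime, n_bins: int = 20,
               mode: str = "equal_width") -> pd.DataFrame:
    """Bin every gene of a genes x cells matrix; returns genes x bins."""
    out = np.empty((expr.shape[0], n_bins))
    X = expr.to_numpy(float)
    for g in range(X.shape[0]):
        out[g], _ = bin_pseudotime(X[g], pseudotime, n_bins=n_bins, mode=mode)
    return pd.DataFrame(out, index=expr.index, columns=range(n_bins))


# ------------------------------------------------------------ HMM

@dataclass
class HmmFit:
    """Two-state Gaussian HMM fit of one gene's binned profile.

    State 1 ("on") is the state with the larger emission mean.  ``states``
    is the Viterbi path per bin; ``switch_bins`` are the indices where the
    decoded state changes (the bin at which the change takes effect).
    """

    n_bins: int
    bin_means: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    states: np.ndarray
    switch_bins: list
    loglik_history: list = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_history[-1]


def _gauss_logpdf(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi * sd**2) - (x[:, None] - mean) ** 2 / (2 * sd**2)


def _forward_backward(logB: np.ndarray, logA: np.ndarray, logpi: np.ndarray):
    """Log-space forward-backward; returns (loglik, gamma, xi_sum)."""
    T, S = logB.shape
    la = np.empty((T, S))
    la[0] = logpi + logB[0]
    for t in range(1, T):
        la[t] = logB[t] + scipy.special.logsumexp(la[t - 1][:, None] + logA, axis=0)
    loglik = float(scipy.special.logsumexp(la[-1]))
    lb = np.zeros((T, S))
    for t in range(T - 2, -1, -1):
        lb[t] = scipy.special.logsumexp(logA + (logB[t + 1] + lb[t + 1])[None, :], axis=1)
    lg = la + lb - loglik
    gamma = np.exp(lg)
    xi_sum = np.zeros((S, S))
    for t in range(T - 1):
        lxi = la[t][:, None] + logA + (logB[t + 1] + lb[t + 1])[None, :] - loglik
        xi_sum += np.exp(lxi)
    return loglik, gamma, xi_sum


def _two_means_split(y: np.ndarray):
    """Deterministic 1-D 2-means (Lloyd from the 25th/75th percentiles)."""
    c = np.percentile(y, [25.0, 75.0]).astype(float)
    if c[0] == c[1]:
        c[1] = c[0] + max(1e-6, 1e-3 * (np.std(y) + 1.0))
    for _ in range(100):
        assign = np.abs(y[:, None] - c).argmin(axis=1)
        new = np.array([y[assign == k].mean() if (assign == k).any() else c[k]
                        for k in range(2)])
        if np.allclose(new, c):
            break
        c = new
    return c, assign


def fit_binarize(bin_means, seed: int = 0, max_iter: int = 500,
                 tol: float = 1e-6, min_sd_frac: float = 0.1) -> HmmFit:
    """Fit a 2-state Gaussian HMM to one binned profile and Viterbi-decode.

    Baum-Welch (EM on forward-backward posteriors) from a 2-means split of
    the bin values with a uniform initial state distribution; convergence
    when the log-likelihood gain drops below ``tol``.  Emission standard
    deviations are floored at ``min_sd_frac`` of the data s.d. (with an
    absolute guard at 1e-3 of it): without a substantial floor, EM on a
    short sequence is drawn to the classic degenerate optimum where one
    Gaussian collapses onto a single observation.  The per-iteration
    log-likelihood must be nondecreasing (checked; a decrease beyond
    numerical noise raises).
    """
    y = np.asarray(bin_means, float)
    if y.size < 5:
        raise ValueError("need at least 5 bins")
    data_sd = float(np.std(y))
    floor = max(min_sd_frac * data_sd, 1e-3 * data_sd, 1e-9)

    centers, assign = _two_means_split(y)
    order = np.argsort(centers)
    means = centers[order].astype(float)
    sds = np.empty(2)
    for k in range(2):
        grp = y[assign == order[k]]
        sds[k] = max(np.std(grp) if grp.size else data_sd, floor, 0.1 * data_sd + 1e-12)
    pi = np.array([0.5, 0.5])
    A = np.array([[0.9, 0.1], [0.1, 0.9]])

    history = []
    for _it in range(max_iter):
        logB = _gauss_logpdf(y, means, sds)
        loglik, gamma, xi_sum = _forward_backward(
            logB, np.log(np.maximum(A, 1e-300)), np.log(np.maximum(pi, 1e-300)))
        if history and loglik < history[-1] - 1e-6 * max(1.0, abs(history[-1])):
            raise RuntimeError("EM log-likelihood decreased; numerical failure")
        converged = bool(history) and loglik - history[-1] < tol
        history.append(loglik)
        if converged:
            break
        pi = gamma[0] / gamma[0].sum()
        denom = gamma[:-1].sum(axis=0)
        A = xi_sum / np.maximum(denom[:, None], 1e-300)
        A /= A.sum(axis=1, keepdims=True)
        w = gamma.sum(axis=0)
        means = (gamma * y[:, None]).sum(axis=0) / np.maximum(w, 1e-300)
        var = (gamma * (y[:, None] - means) ** 2).sum(axis=0) / np.maximum(w, 1e-300)
        sds = np.maximum(np.sqrt(var), floor)

    # relabel so state 1 is "on" (larger mean)
    if means[0] > means[1]:
        means, sds, pi = means[::-1].copy(), sds[::-1].copy(), pi[::-1].copy()
        A = A[::-1, ::-1].copy()

    states = viterbi(y, means, sds, A, pi)
    switches = [int(i) for i in np.flatnonzero(np.diff(states) != 0) + 1]
    return HmmFit(n_bins=y.size, bin_means=y, transmat=A, startprob=pi,
                  means=means, sds=sds, states=states, switch_bins=switches,
                  loglik_history=history)


def viterbi(y: np.ndarray, means: np.ndarray, sds: np.ndarray,
            transmat: np.ndarray, startprob: np.ndarray) -> np.ndarray:
    """Most probable state path of a Gaussian-emission HMM."""
    y = np.asarray(y, float)
    logB = _gauss_logpdf(y, np.asarray(means, float), np.asarray(sds, float))
    logA = np.log(np.maximum(np.asarray(transmat, float), 1e-300))
    delta = np.log(np.maximum(np.asarray(startprob, float), 1e-300)) + logB[0]
    T, S = logB.shape
    back = np.zeros((T, S), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def binarize_genes(bin_mean_matrix: pd.DataFrame, seed: int = 0):
    """Fit/decode every gene of a genes x bins matrix.

    Returns ``(states_df, fits)`` with one 0/1 row per gene and the
    per-gene :class:`HmmFit` objects.
    """
    fits = {}
    states = np.empty(bin_mean_matrix.shape, dtype=int)
    for i, gene in enumerate(bin_mean_matrix.index):
        fit = fit_binarize(bin_mean_matrix.iloc[i].to_numpy(), seed=seed)
        fits[gene] = fit
        states[i] = fit.states
    return pd.DataFrame(states, index=bin_mean_matrix.index,
                        columns=bin_mean_matrix.columns), fits


# ---------------------------------------------------- catalogs, overlap

def filter_by_catalog(table: CorrelationTable | pd.DataFrame, catalog) -> pd.DataFrame:
    """Restrict a correlation table (or gene frame) to catalog members."""
    cat = set(catalog)
    if not cat:
        raise ValueError("empty catalog")
    df = table.table if isinstance(table, CorrelationTable) else table
    out = df[df["gene"].isin(cat)].copy()
    if out.empty:
        log.warning("catalog filter produced an empty table")
    return out


@dataclass
class OverlapResult:
    """Hypergeometric overlap of two gene lists from a common universe."""

    size_a: int
    size_b: int
    universe: int
    intersection: int
    p: float
    shared: list

    def to_dict(self) -> dict:
        return {
            "size_a": self.size_a, "size_b": self.size_b, "universe": self.universe,
            "intersection": self.intersection, "p": self.p, "shared": self.shared,
        }


def overlap_significance(list_a, list_b, universe_size: int) -> OverlapResult:
    """Upper-tail hypergeometric P of the observed list overlap."""
    a, b = set(list_a), set(list_b)
    if universe_size < max(len(a), len(b)):
        raise ValueError("universe smaller than a list")
    shared = sorted(a & b)
    k = len(shared)
    p = float(scipy.stats.hypergeom.sf(k - 1, universe_size, len(b), len(a)))
    return OverlapResult(size_a=len(a), size_b=len(b), universe=universe_size,
                         intersection=k, p=min(p, 1.0), shared=shared)


def expression_cv_report(log_expr: pd.DataFrame, group_flags: pd.Series) -> dict:
    """Coefficient of variation of per-gene mean expression, two gene groups.

    Used to contrast lncRNAs against protein-coding genes; groups are
    compared by a two-sided rank-sum test on per-gene CVs.
    """
    means = log_expr.mean(axis=1)
    sds = log_expr.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (sds / means.abs()).replace([np.inf, -np.inf], np.nan).dropna()
    flags = group_flags.reindex(cv.index).fillna(False).astype(bool)
    a = cv[flags]
    b = cv[~flags]
    p = float(scipy.stats.mannwhitneyu(a, b, alternative="two-sided").pvalue) \
        if len(a) >= 2 and len(b) >= 2 else float("nan")
    return {"cv_group": float(a.median()) if len(a) else float("nan"),
            "cv_rest": float(b.median()) if len(b) else float("nan"),
            "p": p, "n_group": int(len(a)), "n_rest": int(len(b))}
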