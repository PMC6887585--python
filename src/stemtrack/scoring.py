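"""Per-cell signature scores, cycling-cell calling and group comparisons.

Signature activity is summarized per cell either as the arithmetic mean of
the set's log expression (used for the stemness, invasion and cell-cycle
scores) or as a rank-based activity score in [-1, 1] that depends only on
the within-cell expression ranks of the set genes (a light-weight stand-in
for kernel-based pathway activity estimates).  Cycling cells are called by
a median + m*MAD rule on the G1/S and G2/M scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

log = logging.getLogger(__name__)


@dataclass
class CyclingCall:
    """Per-cell cycling flags plus the thresholds that produced them."""

    table: pd.DataFrame  # columns g1s, g2m, cycling
    m: float
    thresholds: dict
    combine: str = "or"

    @property
    def cycling(self) -> pd.Series:
        return self.table["cycling"]


def signature_score(log_expr: pd.DataFrame, gene_set,
                    method: str = "mean_expression") -> pd.Series:
    """Score one gene set per cell.

    ``mean_expression``: mean log expression over the set.
    ``rank_activity``: mean within-cell rank of the set genes, rescaled so
    the top-|S| genes of a cell give +1 and the bottom-|S| give -1.
    Absent set genes are dropped with a warning; an empty effective set
    raises.
    """
    present = [g for g in gene_set if g in log_expr.index]
    missing = len(list(gene_set)) - len(present)
    if missing:
        log.warning("%d set genes absent from the matrix; dropped", missing)
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    if method == "mean_expression":
        return log_expr.loc[present].mean(axis=0)
    if method == "rank_activity":
        G = log_expr.shape[0]
        S = len(present)
        if S >= G:
            raise ValueError("set covers the whole matrix; rank activity undefined")
        ranks = log_expr.rank(axis=0, method="average")
        mean_rank = ranks.loc[present].mean(axis=0)
        mid = (G + 1) / 2.0
        return (mean_rank - mid) / ((G - S) / 2.0)
    raise ValueError(f"unknown scoring method {method!r}")


def score_table(log_expr: pd.DataFrame, signatures,
                method: str = "mean_expression") -> pd.DataFrame:
    """Cells x signatures score matrix for a SignatureSet."""
    cols = {}
    for name in signatures.names():
        cols[name] = signature_score(log_expr, signatures[name], method=method)
    return pd.DataFrame(cols)


def _robust_spread(x: np.ndarray) -> tuple[float, str]:
    """MAD of ``x``; mean absolute deviation from the median as fallback.

    A zero MAD (majority of identical scores) would make the threshold
    vacuous, so the spread falls back to the mean absolute deviation from
    the median, which still reacts to isolated outliers.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad > 0:
        return float(mad), "mad"
    fallback = float(np.mean(np.abs(x - med)))
    log.warning("MAD is zero; falling back to mean absolute deviation (%.4g)", fallback)
    return fallback, "mean_abs_dev"


def call_cycling(scores: pd.DataFrame, m: float = 3.0, combine: str = "or") -> CyclingCall:
    """Flag cycling cells: score above median + m * MAD in either phase.

    ``scores`` must have ``g1s`` and ``g2m`` columns (case-insensitive).
    ``combine`` chooses whether exceeding one phase suffices ("or") or
    both are required ("and"); the choice is recorded in the result.
    """
    colmap = {c.lower(): c for c in scores.columns}
    if "g1s" not in colmap or "g2m" not in colmap:
        raise ValueError("scores must contain g1s and g2m columns")
    thresholds = {}
    exceed = {}
    for phase in ("g1s", "g2m"):
        x = scores[colmap[phase]].to_numpy(float)
        med = float(np.median(x))
        spread, kind = _robust_spread(x)
        thr = med + m * spread
        thresholds[phase] = {"median": med, "spread": spread, "spread_kind": kind,
                             "threshold": thr}
        exceed[phase] = x > thr
    if combine == "or":
        flag = exceed["g1s"] | exceed["g2m"]
    elif combine == "and":
        flag = exceed["g1s"] & exceed["g2m"]
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    table = pd.DataFrame(
        {"g1s": scores[colmap["g1s"]], "g2m": scores[colmap["g2m"]], "cycling": flag},
        index=scores.index,
    )
    return CyclingCall(table=table, m=m, thresholds=thresholds, combine=combine)


def compare_groups(scores: pd.DataFrame, group_labels, min_size: int = 2) -> dict:
    """Pairwise two-sided Wilcoxon rank-sum P values per signature.

    Returns ``{signature: symmetric DataFrame of P values}``; pairs with a
    group smaller than ``min_size`` are skipped (NaN).
    """
    labels = pd.Series(group_labels, index=scores.index)
    groups = sorted(labels.unique(), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for sig in scores.columns:
        P = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
        for i, a in enumerate(groups):
            P.loc[a, a] = 1.0
            for b in groups[i + 1:]:
                xa = scores.loc[labels == a, sig].to_numpy(float)
                xb = scores.loc[labels == b, sig].to_numpy(float)
                if xa.size < min_size or xb.size < min_size:
                    continue
                p = scipy.stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                             method="auto").pvalue
                P.loc[a, b] = P.loc[b, a] = float(min(p, 1.0))
        out[sig] = P
    return out
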