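"""Synthetic multi-patient scRNA-seq generator with planted ground truth.

The generator emulates the statistical structure of a branched tumor
progression captured by single-cell RNA-seq of glioblastoma:

* several patients, each contributing cells with an additive per-patient,
  per-gene offset on the log2 scale;
* a mixture of tumor and normal cells, where only tumor cells carry the
  planted chromosome-segment copy-number shifts;
* a latent progression coordinate ``t`` in [0, 1] on tumor cells, along
  which stem-signature genes lose and invasion-signature genes gain
  expression (optionally with a single bifurcation into an invasive and a
  proliferative branch);
* a cycling subpopulation with boosted G1/S and G2/M signature genes;
* stably expressed housekeeping genes (high mean, reduced dispersion, no
  patient offset, no trend, no CNV overlap) that can act as controls;
* negative-binomial counts with logistic mean-dependent dropout, and a TPM
  matrix derived from the counts by column scaling to 1e6.

Every random draw flows from ``SynthConfig.seed``; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io as stio
from ._types import ExpressionMatrix, SignatureSet, make_gene_map

#: branch labels used by the one_branch topology
TRUNK, BRANCH_INVASIVE, BRANCH_ALT, MAIN = "trunk", "invasive", "alt", "main"


@dataclass
class SynthConfig:
    """Study-design parameters of the simulated cohort.

    ``cnv_segments`` entries are ``(chromosome, start_ordinal, end_ordinal,
    log2_shift)`` with the end ordinal exclusive; shifts apply to tumor
    cells only.  ``trend_effect`` is the total log2-fold change of a
    signature gene across the full latent-time span.  ``dropout_midpoint``
    set to ``None`` disables dropout.
    """

    n_patients: int = 4
    cells_per_patient: int = 100
    n_genes: int = 2000
    n_chromosomes: int = 10
    normal_cell_fraction: float = 0.3
    cnv_segments: tuple = ((1, 10, 130, 0.5),)
    topology: str = "linear"  # {"linear", "one_branch"}
    branch_time: float = 0.5
    stem_set_size: int = 50
    invasive_set_size: int = 50
    g1s_set_size: int = 30
    g2m_set_size: int = 30
    alt_branch_set_size: int = 50
    trend_effect: float = 2.0
    housekeeping_count: int = 98
    cycling_fraction: float = 0.1
    cycling_boost: float = 2.0
    patient_effect_sd: float = 0.5
    nb_dispersion: float = 0.3
    dropout_midpoint: float | None = 0.0
    dropout_slope: float = 1.5
    baseline_log2_mean: float = 4.5
    baseline_log2_sd: float = 1.5
    housekeeping_log2_mean: float = 6.0
    housekeeping_log2_sd: float = 0.5
    housekeeping_dispersion_scale: float = 0.25
    tf_fraction: float = 0.25
    lncrna_fraction: float = 0.1
    cnv_window_hint: int = 100
    seed: int = 0

    def validate(self) -> None:
        for name in ("normal_cell_fraction", "cycling_fraction", "tf_fraction", "lncrna_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.topology not in ("linear", "one_branch"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 0.0 < self.branch_time < 1.0:
            raise ValueError("branch_time must lie strictly inside (0, 1)")
        sizes = (
            self.stem_set_size + self.invasive_set_size + self.g1s_set_size
            + self.g2m_set_size + self.alt_branch_set_size + self.housekeeping_count
        )
        if sizes >= self.n_genes:
            raise ValueError("signature + housekeeping set sizes must sum to < n_genes")
        chrom_sizes = _chromosome_sizes(self.n_genes, self.n_chromosomes)
        for chrom, start, end, _shift in self.cnv_segments:
            if chrom not in chrom_sizes:
                raise ValueError(f"cnv segment on unknown chromosome {chrom}")
            if not (0 <= start < end <= chrom_sizes[chrom]):
                raise ValueError(
                    f"cnv segment ({chrom}, {start}, {end}) outside gene ordinals "
                    f"0..{chrom_sizes[chrom]}"
                )
        small = [c for c, s in chrom_sizes.items() if s < self.cnv_window_hint]
        if small:
            warnings.warn(
                f"chromosomes {small} have fewer genes than the intended CNV window "
                f"({self.cnv_window_hint}); smoothing will truncate heavily",
                stacklevel=2,
            )


@dataclass
class SynthTruth:
    """Ground truth of a generated dataset.

    ``cells``: per-cell patient, is_tumor, latent_time (NaN for normal
    cells), branch, is_cycling.  ``genes``: chromosome, ordinal, signature
    memberships, housekeeping/TF/lncRNA flags and the true trend sign
    (-1 stem, +1 invasive, 0 otherwise).
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    signatures: SignatureSet = field(default_factory=SignatureSet)


def _chromosome_sizes(n_genes: int, n_chromosomes: int) -> dict:
    base = n_genes // n_chromosomes
    rem = n_genes - base * n_chromosomes
    return {c + 1: base + (1 if c < rem else 0) for c in range(n_chromosomes)}


def _gene_layout(config: SynthConfig):
    sizes = _chromosome_sizes(config.n_genes, config.n_chromosomes)
    chroms = np.concatenate([np.full(s, c) for c, s in sizes.items()])
    ordinals = np.concatenate([np.arange(s) for s in sizes.values()])
    names = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    return names, chroms, ordinals


def generate_dataset(config: SynthConfig):
    """Simulate one cohort.

    Returns ``(counts, tpm, gene_map, truth)`` where ``counts`` and ``tpm``
    are :class:`ExpressionMatrix` objects, ``gene_map`` is a gene/
    chromosome/ordinal frame in smoothing order, and ``truth`` is a
    :class:`SynthTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    n_cells = config.n_patients * config.cells_per_patient

    genes, chroms, ordinals = _gene_layout(config)

    # --- per-gene roles: signature sets avoid CNV segments so the planted
    # copy-number signal never doubles as a trend signal
    in_segment = np.zeros(n_genes, dtype=bool)
    for chrom, start, end, _shift in config.cnv_segments:
        in_segment |= (chroms == chrom) & (ordinals >= start) & (ordinals < end)
    eligible = np.flatnonzero(~in_segment)
    need = (
        config.stem_set_size + config.invasive_set_size + config.g1s_set_size
        + config.g2m_set_size + config.alt_branch_set_size + config.housekeeping_count
    )
    if need > eligible.size:
        raise ValueError("not enough genes outside CNV segments for the requested sets")
    picked = rng.choice(eligible, size=need, replace=False)
    cursor = 0

    def take(k):
        nonlocal cursor
        out = picked[cursor:cursor + k]
        cursor += k
        return out

    stem_idx = take(config.stem_set_size)
    inv_idx = take(config.invasive_set_size)
    g1s_idx = take(config.g1s_set_size)
    g2m_idx = take(config.g2m_set_size)
    alt_idx = take(config.alt_branch_set_size)
    hk_idx = take(config.housekeeping_count)

    is_stem = np.zeros(n_genes, bool); is_stem[stem_idx] = True
    is_inv = np.zeros(n_genes, bool); is_inv[inv_idx] = True
    is_g1s = np.zeros(n_genes, bool); is_g1s[g1s_idx] = True
    is_g2m = np.zeros(n_genes, bool); is_g2m[g2m_idx] = True
    is_alt = np.zeros(n_genes, bool); is_alt[alt_idx] = True
    is_hk = np.zeros(n_genes, bool); is_hk[hk_idx] = True

    is_tf = rng.random(n_genes) < config.tf_fraction
    is_lnc = (rng.random(n_genes) < config.lncrna_fraction) & ~is_hk

    # --- baselines
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    baseline[is_hk] = rng.normal(
        config.housekeeping_log2_mean, config.housekeeping_log2_sd, config.housekeeping_count
    )

    # --- per-cell design
    patients = np.repeat([f"P{p + 1}" for p in range(config.n_patients)],
                         config.cells_per_patient)
    cell_ids = np.array([f"C{i:05d}" for i in range(n_cells)])
    is_tumor = np.ones(n_cells, bool)
    for p in range(config.n_patients):
        block = slice(p * config.cells_per_patient, (p + 1) * config.cells_per_patient)
        n_norm = int(round(config.normal_cell_fraction * config.cells_per_patient))
        which = rng.choice(config.cells_per_patient, size=n_norm, replace=False)
        flags = np.ones(config.cells_per_patient, bool)
        flags[which] = False
        is_tumor[block] = flags

    latent_t = np.full(n_cells, np.nan)
    latent_t[is_tumor] = rng.uniform(0.0, 1.0, int(is_tumor.sum()))

    branch = np.array([MAIN] * n_cells, dtype=object)
    if config.topology == "one_branch":
        branch[:] = TRUNK
        past = is_tumor & (latent_t > config.branch_time)
        picks = rng.random(n_cells) < 0.5
        branch[past & picks] = BRANCH_INVASIVE
        branch[past & ~picks] = BRANCH_ALT
    branch[~is_tumor] = "normal"

    is_cycling = np.zeros(n_cells, bool)
    is_cycling[is_tumor] = rng.random(int(is_tumor.sum())) < config.cycling_fraction

    patient_offsets = rng.normal(0.0, config.patient_effect_sd,
                                 (config.n_patients, n_genes))
    patient_offsets[:, is_hk] = 0.0  # housekeeping genes are stable across patients

    # --- assemble log2 means, genes x cells
    log2_mean = np.tile(baseline[:, None], (1, n_cells)).astype(float)

    tum = np.flatnonzero(is_tumor)
    t = latent_t[tum]
    # stem genes fall along latent time everywhere
    log2_mean[np.ix_(is_stem, tum)] -= config.trend_effect * t[None, :]
    # invasive genes rise; on one_branch they plateau on the alternative branch,
    # which instead ramps its own program genes past the bifurcation
    if config.topology == "linear":
        inv_time = t
    else:
        inv_time = np.minimum(t, config.branch_time)
        on_inv = branch[tum] == BRANCH_INVASIVE
        inv_time = inv_time + np.where(on_inv, np.maximum(t - config.branch_time, 0.0), 0.0)
        alt_time = np.where(branch[tum] == BRANCH_ALT,
                            np.maximum(t - config.branch_time, 0.0), 0.0)
        log2_mean[np.ix_(is_alt, tum)] += config.trend_effect * alt_time[None, :]
    log2_mean[np.ix_(is_inv, tum)] += config.trend_effect * inv_time[None, :]

    # CNV shifts in tumor cells only
    for chrom, start, end, shift in config.cnv_segments:
        seg = (chroms == chrom) & (ordinals >= start) & (ordinals < end)
        log2_mean[np.ix_(seg, tum)] += shift

    cyc = np.flatnonzero(is_cycling)
    if cyc.size:
        log2_mean[np.ix_(is_g1s | is_g2m, cyc)] += config.cycling_boost

    for p in range(config.n_patients):
        cols = np.flatnonzero(patients == f"P{p + 1}")
        log2_mean[:, cols] += patient_offsets[p][:, None]

    # --- counts: negative binomial via gamma-poisson, then logistic dropout
    mu = np.power(2.0, log2_mean)
    alpha = np.full(n_genes, float(config.nb_dispersion))
    alpha[is_hk] *= config.housekeeping_dispersion_scale
    counts = np.empty((n_genes, n_cells), dtype=np.int64)
    pos = alpha > 0
    if pos.any():
        shape = 1.0 / alpha[pos]
        lam = rng.gamma(shape[:, None], mu[pos] * alpha[pos][:, None])
        counts[pos] = rng.poisson(lam)
    if (~pos).any():
        counts[~pos] = rng.poisson(mu[~pos])

    if config.dropout_midpoint is not None:
        p_drop = expit(-config.dropout_slope * (log2_mean - config.dropout_midpoint))
        counts[rng.random(counts.shape) < p_drop] = 0

    counts_df = pd.DataFrame(counts, index=genes, columns=cell_ids)
    counts_df.index.name = "gene"

    colsum = counts_df.sum(axis=0).to_numpy().astype(float)
    safe = np.where(colsum > 0, colsum, 1.0)
    tpm_df = counts_df / safe * 1e6

    gene_map = make_gene_map(genes, chroms, ordinals)

    trend_sign = np.where(is_stem, -1, np.where(is_inv, 1, 0))
    truth_genes = pd.DataFrame(
        {
            "gene": genes, "chromosome": chroms, "ordinal": ordinals,
            "stem": is_stem, "invasive": is_inv, "g1s": is_g1s, "g2m": is_g2m,
            "alt_branch": is_alt, "housekeeping": is_hk, "tf": is_tf,
            "lncrna": is_lnc, "trend_sign": trend_sign,
        }
    )
    truth_cells = pd.DataFrame(
        {
            "cell": cell_ids, "patient": patients, "is_tumor": is_tumor,
            "latent_time": latent_t, "branch": branch, "is_cycling": is_cycling,
        }
    )
    sig = SignatureSet()
    sig.add("STEM", genes[stem_idx], "planted stemness signature")
    sig.add("INVASIVE", genes[inv_idx], "planted invasion signature")
    sig.add("G1S", genes[g1s_idx], "planted G1/S program")
    sig.add("G2M", genes[g2m_idx], "planted G2/M program")
    sig.add("ALT_BRANCH", genes[alt_idx], "planted alternative-branch program")
    sig.add("HOUSEKEEPING", genes[hk_idx], "planted stable controls")

    truth = SynthTruth(cells=truth_cells, genes=truth_genes, signatures=sig)
    return (
        ExpressionMatrix(counts_df, "counts"),
        ExpressionMatrix(tpm_df, "tpm"),
        gene_map,
        truth,
    )


def write_fixture(dataset, directory: str) -> dict:
    """Persist a generated dataset (counts/TPM TSV + MTX, gene map, truth, GMT).

    Returns a dict of the written paths; everything round-trips through
    :mod:`stemtrack.io`.
    """
    counts, tpm, gene_map, truth = dataset
    stio.ensure_dir(directory)
    import os

    paths = {}
    paths["counts_tsv"] = stio.write_expression_tsv(counts, os.path.join(directory, "counts.tsv"))
    paths["tpm_tsv"] = stio.write_expression_tsv(tpm, os.path.join(directory, "tpm.tsv"))
    paths["counts_mtx"] = stio.write_expression_mtx(counts, os.path.join(directory, "counts.mtx"))
    paths["gene_map"] = stio.write_gene_map(gene_map, os.path.join(directory, "gene_map.tsv"))
    paths["truth_cells"] = stio.write_table(truth.cells, os.path.join(directory, "truth_cells.tsv"))
    paths["truth_genes"] = stio.write_table(truth.genes, os.path.join(directory, "truth_genes.tsv"))
    paths["gmt"] = stio.write_gmt(truth.signatures, os.path.join(directory, "signatures.gmt"))
    return paths
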