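"""End-to-end recovery studies on synthetic cohorts.

Each function here generates data with :mod:`stemtrack.synthetic`, runs
one stage (or the whole chain) of the pipeline, and measures how well the
planted ground truth is recovered.  They back both the reproducibility
script (``scripts/acceptance.py``) and the heavier integration tests, so
the measured numbers always come from a fresh run of the package itself.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from . import cluster as stcluster
from . import cnv as stcnv
from . import dynamics as stdyn
from . import pipeline as stpipe
from . import preprocess as stpre
from . import scoring as stscore
from . import synthetic as stsynth
from . import trajectory as sttraj


def _spawn_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


# ------------------------------------------------------------ CNV screen

def cnv_screen_accuracy(seed: int, n_seeds: int = 5, cells_per_patient: int = 100,
                        n_genes: int = 2000) -> dict:
    """Tumor/normal label accuracy on cohorts with one planted +0.5 segment.

    400 cells (4 patients x 100), 2000 genes, a 120-gene segment at +0.5
    log2 in tumor cells, 30% normal cells; the control profile comes from
    the true normal cells (standing in for an external normal-brain
    reference).  Returns the mean accuracy across seeds.
    """
    accs = []
    for s in _spawn_seeds(seed, n_seeds):
        cfg = stsynth.SynthConfig(
            n_patients=4, cells_per_patient=cells_per_patient, n_genes=n_genes,
            normal_cell_fraction=0.3, cnv_segments=((1, 10, 130, 0.5),), seed=s,
        )
        counts, tpm, gene_map, truth = stsynth.generate_dataset(cfg)
        params = stcnv.CnvParams(window=100)
        cnv = stcnv.infer_cnv(tpm, gene_map, params)
        normal_cells = truth.cells.loc[~truth.cells["is_tumor"], "cell"]
        ref = stcnv.reference_vector(tpm.subset_cells(normal_cells), gene_map, params)
        labels = stcnv.classify_tumor_cells(cnv, ref, params)
        truth_lab = np.where(truth.cells.set_index("cell")["is_tumor"], "tumor", "normal")
        accs.append(float((labels.to_numpy() == truth_lab).mean()))
    return {"accuracy": float(np.mean(accs)), "per_seed": accs,
            "n": n_seeds * 4 * cells_per_patient}


# -------------------------------------------------------- trajectory

def _trajectory_inputs(cfg: stsynth.SynthConfig):
    """Generate a cohort and prepare tumor-cell log expression.

    Log2(TPM + 1) restricted to tumor cells, with per-patient offsets
    regressed out (the trajectory is learned across patients).
    """
    counts, tpm, gene_map, truth = stsynth.generate_dataset(cfg)
    tcells = truth.cells.loc[truth.cells["is_tumor"], "cell"]
    log_expr = np.log2(tpm.data.loc[:, tcells] + 1.0)
    patients = truth.cells.set_index("cell")["patient"].loc[tcells]
    log_expr = stpre.regress_patient_effect(log_expr, patients)
    return log_expr, truth


def pseudotime_recovery(seed: int, n_seeds: int = 5, n_cells: int = 300) -> dict:
    """|Spearman| between inferred pseudotime and latent time, linear topology.

    Cycling cells are called with the median + 3 MAD rule and their
    indicator regressed out first; otherwise the cycling subpopulation
    forms a spurious side branch that distorts pseudotime for those cells.
    """
    rhos = []
    for s in _spawn_seeds(seed, n_seeds):
        cfg = stsynth.SynthConfig(
            n_patients=3, cells_per_patient=n_cells // 3, normal_cell_fraction=0.0,
            n_genes=1200, cnv_segments=(), topology="linear", seed=s,
        )
        log_expr, truth = _trajectory_inputs(cfg)
        g1s = stscore.signature_score(log_expr, truth.signatures["G1S"])
        g2m = stscore.signature_score(log_expr, truth.signatures["G2M"])
        call = stscore.call_cycling(pd.DataFrame({"g1s": g1s, "g2m": g2m}))
        log_expr = stpre.regress_covariates(
            log_expr, call.cycling.astype(float).to_numpy())
        csc = stscore.signature_score(log_expr, truth.signatures["STEM"])
        res = stpipe.fit_progression_trajectory(log_expr, csc, seed=s)
        rooted = res.trajectory
        lt = truth.cells.set_index("cell")["latent_time"].loc[rooted.cells]
        rho = scipy.stats.spearmanr(rooted.pseudotime.to_numpy(), lt.to_numpy()).statistic
        rhos.append(abs(float(rho)))
    return {"abs_spearman": float(np.mean(rhos)), "per_seed": rhos, "n": n_seeds * n_cells}


def _fate_split(rooted, inv_scores, alt_scores):
    """States downstream of the divergence of the two fate terminals.

    Returns ``(states_toward_invasive, states_toward_alt)`` or None when
    the tree does not separate the two fates.
    """
    try:
        term_i = sttraj.terminal_state_by_score(rooted, inv_scores)
        term_a = sttraj.terminal_state_by_score(rooted, alt_scores)
    except ValueError:
        return None
    if term_i == term_a:
        return None
    sg = sttraj.state_graph(rooted)
    rs = sttraj.root_state(rooted)
    path_i = nx.shortest_path(sg, rs, term_i)
    path_a = nx.shortest_path(sg, rs, term_a)
    common = set(path_i) & set(path_a)
    return ([s for s in path_i if s not in common],
            [s for s in path_a if s not in common])


def branch_recovery(seed: int, n_seeds: int = 5, n_cells: int = 300) -> dict:
    """Branch-assignment accuracy on one-bifurcation cohorts.

    The two fate terminals are located by their invasive / alternative
    program scores; cells in states past the divergence of the two
    root-to-terminal paths are assigned to the corresponding fate, and
    accuracy is measured over cells that both truly lie past the planted
    bifurcation and were assigned to a fate.  A tree that fails to
    separate the fates scores 0.
    """
    accs = []
    for s in _spawn_seeds(seed, n_seeds):
        cfg = stsynth.SynthConfig(
            n_patients=3, cells_per_patient=n_cells // 3, normal_cell_fraction=0.0,
            n_genes=1200, cnv_segments=(), topology="one_branch", seed=s,
        )
        log_expr, truth = _trajectory_inputs(cfg)
        csc = stscore.signature_score(log_expr, truth.signatures["STEM"])
        inv = stscore.signature_score(log_expr, truth.signatures["INVASIVE"])
        alt = stscore.signature_score(log_expr, truth.signatures["ALT_BRANCH"])
        rooted = stpipe.fit_progression_trajectory(log_expr, csc, seed=s).trajectory
        split = _fate_split(rooted, inv, alt)
        if split is None:
            accs.append(0.0)
            continue
        states_i, states_a = split
        pred = pd.Series("other", index=rooted.cells, dtype=object)
        pred[rooted.states.isin(states_i)] = "inv"
        pred[rooted.states.isin(states_a)] = "alt"
        tr = truth.cells.set_index("cell").loc[rooted.cells]
        sel = tr["branch"].isin([stsynth.BRANCH_INVASIVE, stsynth.BRANCH_ALT]) \
            & pred.isin(["inv", "alt"])
        if sel.sum() == 0:
            accs.append(0.0)
            continue
        t = (tr["branch"][sel] == stsynth.BRANCH_INVASIVE).to_numpy()
        p = (pred[sel] == "inv").to_numpy()
        accs.append(float((t == p).mean()))
    return {"accuracy": float(np.mean(accs)), "per_seed": accs, "n": n_seeds * n_cells}


def stem_invasion_path(seed: int, n_seeds: int = 5, n_cells: int = 300) -> dict:
    """Score trends along the extracted stem-to-invasion path.

    Correlates the per-cell stemness and invasion scores with pseudotime
    along the path from the CSC-rooted leaf to the invasive terminal
    state; the planted pattern is a falling CSC and a rising invasive
    score.
    """
    csc_rhos, inv_rhos = [], []
    for s in _spawn_seeds(seed, n_seeds):
        cfg = stsynth.SynthConfig(
            n_patients=3, cells_per_patient=n_cells // 3, normal_cell_fraction=0.0,
            n_genes=1200, cnv_segments=(), topology="one_branch", seed=s,
        )
        log_expr, truth = _trajectory_inputs(cfg)
        csc = stscore.signature_score(log_expr, truth.signatures["STEM"])
        inv = stscore.signature_score(log_expr, truth.signatures["INVASIVE"])
        rooted = stpipe.fit_progression_trajectory(log_expr, csc, seed=s).trajectory
        target = sttraj.terminal_state_by_score(rooted, inv)
        path = sttraj.extract_path(rooted, target)
        pt = rooted.pseudotime.loc[path.cells].to_numpy()
        csc_rhos.append(float(scipy.stats.spearmanr(csc.loc[path.cells], pt).statistic))
        inv_rhos.append(float(scipy.stats.spearmanr(inv.loc[path.cells], pt).statistic))
    return {"csc_spearman": float(np.mean(csc_rhos)),
            "invasive_spearman": float(np.mean(inv_rhos)),
            "csc_per_seed": csc_rhos, "invasive_per_seed": inv_rhos,
            "n": n_seeds * n_cells}


# ------------------------------------------------------------- HMM

def viterbi_bruteforce_agreement(seed: int, n_draws: int = 100, n_bins: int = 5) -> dict:
    """Fraction of random parameter draws where Viterbi matches enumeration."""
    import itertools

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_draws):
        y = rng.normal(0, 1, n_bins)
        means = np.sort(rng.normal(0, 2, 2))
        sds = rng.uniform(0.3, 2.0, 2)
        A = rng.dirichlet([3, 1], 2)
        pi = rng.dirichlet([1, 1])
        path = stdyn.viterbi(y, means, sds, A, pi)
        best, best_lp = None, -np.inf
        for cand in itertools.product((0, 1), repeat=n_bins):
            lp = np.log(pi[cand[0]]) + scipy.stats.norm.logpdf(y[0], means[cand[0]], sds[cand[0]])
            for t in range(1, n_bins):
                lp += np.log(A[cand[t - 1], cand[t]])
                lp += scipy.stats.norm.logpdf(y[t], means[cand[t]], sds[cand[t]])
            if lp > best_lp:
                best, best_lp = cand, lp
        agree += int(tuple(path) == best)
    return {"agreement": agree / n_draws, "n": n_draws}


def hmm_switch_recovery(seed: int, n_seeds: int = 10, n_genes: int = 50,
                        n_bins: int = 20, snr: float = 2.0,
                        n_cells: int = 300) -> dict:
    """Noisy-step simulation: decoded switch bin within +-1 of truth.

    Per gene, ``n_cells`` cells along a pseudotime axis carry a step of
    height ``snr`` times the per-cell noise s.d.; the cells are averaged
    into ``n_bins`` pseudotime bins (as the pipeline does) and the HMM is
    fit to the bin means.  A gene is recovered when the Viterbi path has
    exactly one switch within one bin of the planted step.
    """
    rates = []
    for s in _spawn_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        hits = 0
        pt = np.linspace(0.0, 1.0, n_cells)
        for _ in range(n_genes):
            true_switch = int(rng.integers(3, n_bins - 3))
            step_at = true_switch / n_bins
            values = np.where(pt >= step_at, snr, 0.0) + rng.normal(0, 1.0, n_cells)
            y, _empty = stdyn.bin_pseudotime(values, pt, n_bins=n_bins)
            fit = stdyn.fit_binarize(y, seed=s)
            if len(fit.switch_bins) == 1 and abs(fit.switch_bins[0] - true_switch) <= 1:
                hits += 1
        rates.append(hits / n_genes)
    return {"recovery": float(np.mean(rates)), "per_seed": rates,
            "n": n_seeds * n_genes}


# -------------------------------------------------- DE and clustering

def de_null_fpr(seed: int, n_seeds: int = 20, n_cells: int = 200,
                n_genes: int = 300, z_cut: float = 2.58) -> dict:
    """Fraction of null genes flagged under random label permutations."""
    fracs = []
    for s in _spawn_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        mu = rng.uniform(0.5, 4.0, n_genes)
        X = rng.poisson(mu[:, None], (n_genes, n_cells)).astype(float)
        expr = pd.DataFrame(np.log2(X + 1), index=[f"g{i}" for i in range(n_genes)])
        labels = rng.permutation(np.repeat([0, 1], n_cells // 2))
        de = stcluster.differential_expression(expr, labels, z_cut=z_cut)
        de = de[de["cluster"] == 0]
        fracs.append(float(de["significant"].mean()))
    return {"fpr": float(np.mean(fracs)), "per_seed": fracs, "n": n_seeds * n_genes}


def blob_clustering_ari(seed: int, n_seeds: int = 10, n_per_blob: int = 100,
                        separation: float = 10.0) -> dict:
    """ARI of density-peak clustering on two well-separated Gaussian blobs."""
    aris = []
    for s in _spawn_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        a = rng.normal([0, 0], 1.0, (n_per_blob, 2))
        b = rng.normal([separation, 0], 1.0, (n_per_blob, 2))
        X = np.vstack([a, b])
        truth = np.repeat([0, 1], n_per_blob)
        labels, _ = stcluster.density_peak_cluster(X)
        aris.append(float(adjusted_rand_score(truth, labels)))
    return {"ari": float(np.mean(aris)), "per_seed": aris, "n": n_seeds * 2 * n_per_blob}
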