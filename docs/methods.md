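# Methods

This note documents the models behind `stemtrack`, the assumptions of the
synthetic-data generator, and the numerical choices that were genuinely
open. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohorts

`stemtrack.synthetic.generate_dataset` draws, per gene g and cell c, a log2
mean assembled in this order:

1. baseline `b_g ~ Normal(4.5, 1.5)` (housekeeping genes instead
   `Normal(6.0, 0.5)`);
2. tumor cells get a latent time `t_c ~ Uniform(0, 1)`; with the
   `one_branch` topology, cells past `branch_time` (default 0.5) are split
   evenly between an *invasive* and an *alternative* branch;
3. stem-set genes add `−trend_effect · t_c`, invasive-set genes add
   `+trend_effect · t_c` (on the alternative branch the invasive ramp
   plateaus at the bifurcation, while a dedicated 50-gene alternative-branch
   program ramps instead). `trend_effect` defaults to 2 — a four-fold change
   over the full span;
4. each planted CNV segment adds its log2 shift in tumor cells only;
5. cycling cells (a `cycling_fraction = 0.1` Bernoulli draw among tumor
   cells) add `cycling_boost = 2` to the G1/S and G2/M sets;
6. a per-patient, per-gene offset `Normal(0, patient_effect_sd = 0.5)` is
   shared by all cells of a patient (zero for housekeeping genes — they are
   the stable controls);
7. counts are negative-binomial (gamma–Poisson) with dispersion 0.3
   (housekeeping: ×0.25); `dispersion = 0` degenerates to Poisson;
8. dropout zeroes a count with probability
   `sigmoid(−slope · (log2mean − midpoint))`, midpoint 0 and slope 1.5, so
   loss concentrates at low expression and housekeeping genes are rarely
   dropped; `dropout_midpoint = None` disables it;
9. TPM columns are the counts rescaled to sum to 1e6 (gene length is not
   modeled; the TPM/counts distinction here is purely the column scaling).

The defaults emulate deep full-length (plate-based) single-cell data: with
2000 genes a cell carries roughly 40–60k counts, tens per detected gene.
Signature sets, housekeeping genes and CNV segments are disjoint by
construction so a planted signal never doubles as another. Ground truth
(`SynthTruth`) records patient, tumor status, latent time, branch, cycling
flag per cell, and set memberships, TF/lncRNA flags and trend sign per gene.

What the generator does **not** emulate: gene-length effects, UMI vs read
chemistry, doublets, ambient RNA, discrete subclone structure beyond the
planted segments, or realistic gene–gene correlation beyond the planted
programs. Passing recovery tests therefore show the pipeline recovers the
modeled structure at realistic noise — not that it is robust to every
artifact of real data.

## CNV screen

Copy number is approximated as the centered moving average of
`log2(TPM + 1)` over a window of 100 flanking genes: the gene itself plus up
to 50 on each side, truncated at chromosome boundaries (total span ≤ 101).
The per-gene cross-cell means are kept (`CnvMatrix.gene_means`) so external
profiles can be placed on the same centered scale.

Classification clusters the centered profiles plus a control-derived
reference pseudo-cell (Ward linkage, Euclidean; cut into `n_cut = 2`
groups). A group is *normal* if it holds the reference or if the mean
squared deviation of its **mean profile** from the reference is within 2×
the reference group's own value. Two choices here deserve a note:

* **Ward, not average linkage.** On simulated cohorts average linkage
  chains, splitting off one or two outlier cells instead of the
  tumor/normal groups; Ward produces the balanced cut the screen needs.
  Linkage remains a parameter.
* **Group-mean deviation, not per-cell magnitude.** After cross-cell
  centering in a tumor-majority cohort, *normal* cells show the larger
  absolute centered values over a planted segment (the cohort mean is
  shifted toward the tumor state), so absolute CNV magnitude misleads.
  Comparing each group's average profile to the control reference is
  invariant to the mixture fraction, and averaging within the group
  suppresses single-cell noise while a shared segment survives.

## Normalization chain

Order: cell QC → per-patient gene filter → Census-style conversion →
scaling factors → RUV → (patient regression at clustering/trajectory time).

* **QC**: detected genes ≥ 3000 and a count-depth proxy ≥ 2e5 by default
  (read-level quality cannot be evaluated from a matrix; totals carry the
  same intent). Both thresholds scale with the data and the report lists
  per-cell reasons.
* **Census-style conversion**: per cell, the mode of the Gaussian kernel
  density of log10 TPM over detected genes (TPM ≥ 0.1) estimates the TPM
  value of one transcript, and relative counts are `TPM / t*`. This is the
  mode-scaling core of the published algorithm; it is monotone and
  scale-invariant per cell, which is all the downstream chain uses.
* **Scaling factors**: library-size totals anchored to geometric mean 1 by
  default; a pooling-deconvolution mode sums cells in rolling depth-ordered
  pools, estimates robust pool-level sizes against an average profile, and
  solves the linear system by least squares. Pools of several sizes
  (p−1, p, p+1) are used because a single ring size yields a circulant
  design with zero eigenvalues (an underdetermined system). Cells with zero
  depth or detected-gene fraction below 25 % of the cohort median are
  dropped and reported ("low transcriptomic diversity"; the threshold is a
  parameter because no published number exists).
* **RUV**: the top k right singular vectors of the row-centered
  housekeeping submatrix define orthonormal cell factors; each gene is
  replaced by its residual (plus mean) after regression on them. `k = 1` by
  default; `k = 0` is the identity. For lncRNA matrices this step is
  skipped (no lncRNA behaves like a housekeeping control); the CLI exposes
  that as `--k 0`.
* **Patient regression**: per gene, subtracting patient means and re-adding
  the grand mean — the exact least-squares solution for patient-indicator
  regression. `regress_covariates` applies the same least-squares removal
  for arbitrary per-cell covariates (used for cell-cycle activity).

## Clustering, differential expression, enrichment

Density-peak clustering computes, per cell, the local density ρ (neighbors
within a cutoff distance, default the 2nd percentile of pairwise distances;
a Gaussian kernel is available) and δ, the distance to the nearest denser
cell (the global density maximum takes the maximum pairwise distance).
Cells with ρ and δ above the thresholds are peaks; all others inherit the
label of their nearest denser neighbor in decreasing-density order. Density
ties break by smaller index, making the assignment deterministic and
order-invariant. Default thresholds (2, 4) match the published values but
are scale-bound to the embedding, so the ρ–δ decision table is always
returned. The embedding is PCA (deterministic), not t-SNE, which in the
original analysis is a visualization.

Differential expression uses a tie-corrected rank-sum z per gene
(cluster vs rest), flagged at |z| > 2.58 (two-sided P < 0.01) — the decision
rule of the original error-model-based statistic, without its Bayesian
machinery. A dropout-aware alternative (`engine="twocomp"`) compares the
expressed (nonzero) component means by a Welch z. Null calibration is part
of the acceptance checks (≈1 % flagged under permuted labels).

Enrichment is the upper-tail hypergeometric probability of the observed
overlap, Benjamini–Hochberg-adjusted across sets, FDR < 0.05.

## Scores and cycling cells

`mean_expression` is the arithmetic mean of the set's log expression;
`rank_activity` is the mean within-cell rank of the set genes rescaled to
[−1, 1] (a light-weight, monotone-invariant stand-in for kernel-based
pathway activity scores — the exact published estimator is a tool of its
own, not re-implemented here). Cycling cells exceed
`median + 3·MAD` in either phase score (the OR rule is recorded in the
output). When the MAD is zero — a majority of identical scores — the spread
falls back to the **mean absolute deviation from the median** rather than
the standard deviation: the standard deviation of, say, [0, 0, 0, 0, 10] is
4, putting the threshold at 12 and hiding the obvious outlier, while the
mean absolute deviation (2) flags exactly it.

## Trajectory

The principal tree is fit by: PCA to `n_dims` (default 4), optional
k-nearest-neighbor averaging of the embedding (default k = 15; suppresses
per-cell noise before geometry is estimated), k-means initialization of
`n_nodes` centroids (default 12), then alternating (a) minimum spanning
tree over centroids and (b) centroid updates toward the soft-assigned cell
mean plus a smoothness pull toward tree neighbors (weight 2.0), until the
largest centroid move falls below 1e-4 of the data scale. Leaf segments
with fewer than 15 assigned cells are pruned. Cells project to the nearest
tree edge; on leaf edges the projection extrapolates beyond the end node so
cells past the tree's end keep their ordering instead of collapsing onto
the last node. Segments delimited by branch points and leaves define
states; pseudotime is geodesic distance from the root leaf (shifted so its
minimum is 0), and the root is the leaf segment with maximal median CSC
score (overridable).

The full workflow (`pipeline.fit_progression_trajectory`) selects ordering
genes by **differential expression between clusters** (k-means in PCA-10
space, rank-sum |z| > 2.58, strongest 400), standardizes each ordering gene
to unit variance, fits the tree, and then runs one **terminal refinement**:
cells beyond the 60th pseudotime percentile are re-clustered (k = 3 on a
3-component PCA of the standardized full matrix), their differential genes
are added to the ordering set, and the tree is refit. The refinement exists
because genes separating the terminal fates vary little over the whole
population and are easy to miss in one pass; without it the bifurcation is
found in only a fraction of simulated cohorts. A dispersion-based selector
(`cluster.select_ordering_genes`, mean > 0.1 plus dispersion above a
binned-median baseline) is also provided, but it favours noisy low-count
genes and is not used by the default workflow.

Two workflow variants are documented for cell-cycle handling: for a linear
progression, cycling cells otherwise form a spurious side spur with
distorted pseudotime, so the cycling indicator (median + 3·MAD call) is
regressed out first; for branched analyses the trajectory is fit without
that regression and the cycling subpopulation simply occupies its own
branch, as it does in the real data.

Branch-dependent expression compares a shared natural cubic spline of
expression on pseudotime (3 internal knots at quantiles) against
branch-specific splines; the statistic is `n·ln(RSS₀/RSS₁)`, chi-square
with the interaction degrees of freedom, BH-adjusted, flagged at
q < 1e-4. Gaussian residuals on log expression stand in for the original
spline/VGAM machinery; the spline basis is the standard natural-spline
construction (linear beyond the boundary knots), which reproduces linear
functions exactly.

## Gene dynamics and the HMM

Spearman correlation with pseudotime uses average ranks; constant genes are
excluded with a note. Top lists take the N strongest positive/negative
genes (N = 1000, capped at a quarter of usable genes on small matrices);
the achieved correlation cutoffs are *reported*, mirroring how the original
thresholds (0.28 / −0.22) arose as consequences of a top-1000 rule rather
than as inputs.

Pseudotime is divided into 20 equal-width bins (equal-count offered);
per-bin means are the HMM observations; empty bins are linearly
interpolated and flagged, and more than 50 % empty raises.

The two-state HMM has Gaussian emissions on the binned means (the cited
discrete-emission formulation would require an arbitrary discretization).
Baum–Welch runs from a deterministic 1-D 2-means split with uniform initial
state probabilities, converging when the log-likelihood gain is below 1e-6
(at most 500 iterations); monotonicity of the log-likelihood is asserted
every iteration. Emission standard deviations are floored at 10 % of the
data s.d. — without a substantial floor, EM on a 20-point sequence is
drawn into the degenerate optimum where one Gaussian collapses onto a
single observation (the floor fraction is a parameter). "On" is the state
with the larger mean; switch bins are where the Viterbi path changes.

The switch-recovery study plants the step in 300 cells (per-cell
signal-to-noise 2) and averages them into the 20 bins exactly as the
pipeline does. This matters: with the noise placed directly on the 20 bin
values at SNR 2, even an exhaustive single-changepoint matched filter with
known parameters locates the switch within ±1 bin only ~87 % of the time,
so per-bin noise at that level is not a regime any decoder can master; the
HMM's actual inputs are bin means whose noise is ~√15 smaller.

Catalog filtering (TFs, lncRNAs) is set intersection preserving ranks, and
cross-dataset replication uses the upper-tail hypergeometric overlap
probability with an explicit universe size (the appropriate universe —
all genes vs all catalog members — is the caller's modeling decision).

## Study sizes used by the acceptance script

CNV screen: 5 cohorts of 400 cells × 2000 genes (one 120-gene +0.5 segment,
30 % normal cells). Trajectory studies: 5 cohorts of 300 tumor cells × 1200
genes per topology. HMM: 100 random Viterbi instances and 10 × 50
noisy-step genes. DE null: 20 permutations of 200 cells × 300 genes.
Density peaks: 10 draws of two 100-point blobs at 10 s.d. separation. Each
study derives its seeds from the script's `--seed` via `SeedSequence`.

## Known limitations

* The principal-tree variant is a deliberately simple substitute for
  reversed-graph-embedding methods; it recovers one bifurcation reliably at
  the generator's effect sizes but is not tuned for deeply nested
  topologies.
* The rank-sum z is a decision-rule-compatible substitute for the original
  Bayesian error-model statistic; their numerical agreement is not
  asserted, only the shared |z| > 2.58 ⇔ P < 0.01 rule and the null
  calibration.
* Census conversion implements only the density-mode scaling; the full
  published estimator has additional terms irrelevant to a monotone
  TPM→count bridge.
* Branch-assignment accuracy is measured over cells the tree actually
  places past the fate divergence; cells in the ambiguous region near the
  bifurcation (where the branch programs have not yet diverged) project to
  the trunk and are not scored — matching what the method claims to decide.
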