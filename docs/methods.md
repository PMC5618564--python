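# Methods

## Data model and input format

The unit of observation is a single cell measured on a qPCR gene panel.
The canonical input is a matrix CSV with header
`cell_id,group,chip,<gene>,...`, one row per cell. A field that is
empty, the literal `NA`, or a numeric value at or above the detection
limit (`max_cycles`, default 40) is read as a failed amplification;
instrument exports spell censoring in all three ways, so all three are
accepted and normalized to a single internal FAILED marker. A Ct of
exactly 40 counts as failed: amplification must occur strictly before
the limit. On output FAILED is always written as an empty field, and
values are written with full round-trip precision, so write–read is an
identity.

## Normalization

Let Ct_{cg} be the cycle threshold of cell *c* at gene *g*, and m_g the
median over successful reactions of gene *g* in the pooled sample — all
cells from both groups and all chips together. Pooling is deliberate:
per-group medians would absorb exactly the group differences the
downstream tests look for. Expression is

x_{cg} = clip(m_g − Ct_{cg}, −B, +B)

with B = 5 cycles by default. Since each PCR cycle is one doubling, m_g
− Ct is already a base-2 logarithm of abundance relative to the gene's
median cell, and B = 5 corresponds to a 2^5 = 32-fold ceiling. Failed
reactions are assigned exactly −B, with a boolean mask distinguishing
them from expressed values that reach −B by clipping. Genes whose every
reaction failed have no median and are dropped with a logged warning
rather than silently zeroed.

Whether the pooled median should be taken over successful reactions only
or with failures counted at the detection limit is genuinely open; the
default is successful-only (`median_policy="expressed"`), with
`"floor_at_limit"` exposed as a switch. Even-count medians use the
midpoint of the central pair. No chip-effect correction is applied
beyond pooled-median centering; the chip label is carried through for
diagnostics.

Floored non-expressers are retained in every downstream computation
(clustering, testing) as a point mass at −B — dropout of a transcript is
part of the biological signal — and the failed fraction per gene and
group is additionally reported on its own.

## Subpopulation discovery

Clustering is Euclidean k-means on the clipped log2 matrix: k-means++
D²-weighted seeding, Lloyd iteration to label convergence, best of
`n_restarts` (default 50) runs by within-cluster sum of squares (WCSS).
Lloyd iteration is implemented in the package rather than delegated
because the contract includes a per-iteration WCSS trace (asserted
non-increasing in the tests), deterministic restart seeding from one
integer, empty-cluster repair (an emptied cluster takes the point
farthest from its centroid, which cannot increase WCSS), and stable
relabeling — clusters are renumbered 1..k by decreasing size, ties by
smallest contained cell index, so "cluster 1" means the same thing
across reruns. scikit-learn's KMeans is used as an independent
cross-check in the test suite, never as the implementation.

The number of clusters is selected with the gap statistic (Tibshirani,
Walther & Hastie): for each k ≤ k_max, Gap(k) = mean_b log W*_{kb} −
log W_k over n_reference = 50 reference datasets drawn uniformly within
the per-gene observed range, with s_k = sd_b(log W*_{kb})·√(1 + 1/B_ref);
the chosen k is the smallest with Gap(k) ≥ Gap(k+1) − s_{k+1}, falling
back to k_max. Reference k-means runs use 10 restarts — selection needs
the shape of the W_k curve, not the exact optimum — while the final
partition uses the full 50. A `--k` override forces a fixed cluster
count (e.g. k = 3 to mirror a known three-subpopulation structure).

Heatmap ordering is scipy agglomerative clustering on cells and genes
(euclidean metric, average linkage by default; ward requires euclidean;
correlation distance refuses constant profiles with advice to use
euclidean), returning the dendrogram leaf order. Composition tables
cross-tabulate cluster against group and report both per-cluster group
fractions and per-group cluster fractions.

## Differential expression

All contrasts use the standard two-sample Kolmogorov–Smirnov test on the
full per-cell value vectors. D is the supremum of |ECDF_a − ECDF_b|
evaluated at every pooled sample point, which is exact under ties — the
floor point mass at −B is a heavy tie by construction. The two-sided
p-value is the asymptotic Kolmogorov probability at √(n_eff)·D with
n_eff = n_a·n_b/(n_a + n_b). With heavy ties the asymptotic p is
conservative (D can only shrink under ties), which the null simulation
confirms empirically (family-wise error ≈ 0.03–0.05 at nominal 0.05).
For small samples an exact permutation p-value enumerates all
C(n_a+n_b, n_a) label assignments; it is the oracle the asymptotic
decisions are tested against (agreement required after Bonferroni on
all fixtures with n_a+n_b ≤ 12) and is available at run time via
`--exact`.

Family-wise error is controlled by Bonferroni: p_adj = min(1, m·p_raw)
with m the number of genes actually tested (after dropping all-dropout
genes), not the nominal panel size — only performed tests are corrected.
Significance is p_adj < α, default α = 0.05 with 0.01 as the documented
stricter preset. Two contrast families are provided: the two biological
groups against each other, and each cluster against all remaining cells
(refused for k = 1, where no "rest" exists; singleton clusters are
tested but flagged low-power). Direction is the sign of the median
difference. Gaussian summaries (sample mean, n−1 standard deviation;
degenerate flagged when n < 2 or sd = 0) are fitted per gene and side
for the display panels only — they never enter the testing.

## Synthetic experiments

The generator works on the Ct scale so the entire preprocessing path —
pooled medians, clipping, flooring, censoring at 40 cycles — is
exercised end to end. Per cell: a subpopulation is drawn from the
cell's group mixing vector; a chip is assigned round-robin; per gene,
Ct ~ Normal(subpop mean + chip offset, subpop sd) truncated to
(0, max_cycles]; with the dropout probability the value becomes a failed
reaction. Identical seeds give byte-identical tables.

Dropout is expression-dependent by default: a logistic function of the
subpopulation mean Ct, p(μ) = 1/(1 + exp(−slope·(μ − midpoint))), with
slope 0.4 per cycle and the midpoint anchored so that the failure rate
at the baseline mean equals the stated baseline dropout. This mirrors
the physics of the assay — weakly expressed transcripts fail to amplify
far more often than abundant ones — and matters statistically: with
dropout spread uniformly at random over all genes, the per-cell floor
spikes mimic extra substructure and the gap statistic over-partitions.
A flat per-gene dropout remains available (`dropout_slope=0`, or
explicit per-gene probabilities).

The default study (`fak_study_spec`) emulates the two-group keratinocyte
design: 48 genes named for a mechanotransduction/ECM panel, WT and KO
groups of 80 cells, three subpopulations with mixing (0.70, 0.20, 0.10)
in WT and (0.15, 0.45, 0.40) in KO — so the minority "activated"
subpopulation is 80% KO by construction. Each subpopulation
overexpresses its own 8-gene marker block by 4 cycles (16-fold): a
FAK-signaling block (Ptk2, Pxn, Src, Itga6, Mapk1, Mapk3, Timp1, Timp2),
an ILK/adhesion block, and the collagen/MMP matrix-remodeling block for
the activated minority; Ptk2 is additionally weakly detected (mean Ct
30) outside the FAK-signaling subpopulation. Baseline mean Ct is 24,
per-gene sd 0.5 cycles — the same noise level used in the null and power
simulations, chosen as a realistic single-assay technical+biological
spread of a few-fold — baseline dropout 0.15, two chips, chip sd 0 by
default so baseline analyses are clean (set `chip_sd` to study batch
offsets).

What the generator does **not** emulate: gene–gene correlation within a
subpopulation beyond the block means (real panels are correlated through
shared pathways), amplification-efficiency differences between assays,
cell-size/lysis covariates, and doublets. Passing recovery tests on this
generator therefore shows the pipeline recovers mixture-of-truncated-
normals structure under realistic dropout and censoring — not that any
particular real dataset contains three subpopulations.

`null_spec` builds the degenerate one-subpopulation design used for the
error-control studies (96 genes, 100 cells/group, sd 0.5, flat dropout
0.15 — all genes sit at the baseline mean, where the flat and logistic
parameterizations coincide), optionally planting per-gene Ct shifts in
the second group for power studies.

## Reproducibility and numerical choices

A single top-level seed fans out to per-stage seeds through numpy's
SeedSequence, so stages are independently reproducible; all derived
seeds are kept below 2^31. k-means distance computations use the
‖x‖² + ‖c‖² − 2x·c expansion clipped at zero; restart ties keep the
first optimum; hierarchical distance ties resolve by scipy's
deterministic merge order. CSV outputs round floats to 6 significant
digits (re-serialization is byte-stable); the Ct matrix itself is
written at full precision for exact round trips. Run manifests record
input digests, all parameters, and a SHA-256 inventory of outputs;
`scqpcr verify` re-hashes them. Figures are not bit-pinned (rendering
backends vary); the CSVs are the contract.

Simulation sizes in the shipped studies — 200 null replicates, 100
power replicates, 50 recovery seeds — put Monte-Carlo standard errors
near 0.015 on the estimated rates, small against the margins being
checked, while keeping each study in the seconds-to-minutes range.

## Known limitations

- The asymptotic KS p-value is used at all sample sizes; below ~25
  cells per side it is approximate (conservative under floor ties), and
  below 5 the code warns. `--exact` switches to the permutation null.
- Bonferroni is intentionally strict; no FDR alternative is offered.
- The gap statistic's uniform-box reference is feature-range based; it
  inherits that method's tendency to merge overlapping subpopulations.
- No imputation, housekeeping normalization, or efficiency correction:
  centering is pooled-median only.
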