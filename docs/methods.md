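# Methods

`monomac` implements a single-cell RNA-seq analysis of colonic
monocyte-to-macrophage differentiation ("monocyte waterfall") contrasted
between two genotypes — control and a conditional knockout (cKO) of CD98hc
(*Slc3a2*) in CX3CR1+ cells.  This note documents the models and procedures,
the parameters that matter, what the synthetic data generator does and does
not emulate, and the numerical choices made where the design was open.

## Pipeline overview

Starting from per-sample 10x-style UMI matrices, the stages run in order:

1. **Merging** — column concatenation without rescaling or downsampling;
   cell barcodes get a `-<k>` sample suffix.
2. **Cell QC** — keep a cell iff log10(library size) ≥ 2.8 (smallest
   admissible integer library 631), log10(detected genes) ≥ 2.6 (smallest
   admissible count 399), mitochondrial UMI fraction ≤ 5%, and zero
   hemoglobin UMIs.  Boundary convention: exclusion is for values strictly
   below the log10 cutoffs and strictly above 5% mitochondrial fraction, so
   equality passes.  Mitochondrial genes are recognized by the
   case-insensitive `mt-` symbol prefix and hemoglobin genes by the
   configurable `Hba*`/`Hbb*` prefix list; both lists are conventions
   exposed in `AnalysisConfig`.
3. **Gene filter** — drop genes with log2(mean CPM) < 0.005, computed on
   QC-passing cells.  "Average log2 CPM" is implemented as the log of the
   mean CPM (not the mean of logs), the convention of the abundance filters
   this stage mirrors.
4. **Normalization** — deconvolution size factors: cells are ordered on a
   ring by library size (interleaved low/high so pools mix depths), pooled
   profiles over sliding windows of sizes {21, 41, 61, 81, 101} are
   compared with the average pseudo-cell by a gene-wise median ratio, and
   the linear system (pool sums of factors ≈ pooled estimates) is solved by
   least squares via its normal equations, with low-weight identity rows
   (weight 0.01) guaranteeing full rank.  Factors are scaled to unit mean;
   optional pre-clustering stratifies the estimate and rescales clusters by
   median pseudo-cell ratios.  Expression is `log2(count/factor + 1)`.
5. **Variance decomposition and denoised PCA** — a loess (tricube, local
   linear) trend with span 0.05 is fitted to per-gene variance vs mean of
   log-expression; the fitted value is the technical component and the
   residual the biological component (total = technical + biological by
   construction; evaluation outside the fitted range clamps to the nearest
   point, and the effective span is floored at 5 points for tiny inputs).
   PCA (centering only, no scaling) retains the smallest d such that the
   discarded variance is at most the summed technical variance, with a
   floor of d = 2.  The top 500 genes by biological variance feed the t-SNE
   (perplexity 30, Barnes–Hut, fixed seed); ties in the HVG ranking break
   lexicographically on gene id.
6. **Clustering** — Ward linkage on Euclidean distances between cells in
   normalized log-expression space (all filtered genes, not PC scores), cut
   by an adaptive top-down rule: a branch splits into its two children when
   the merge-height gap (branch height minus tallest child height) exceeds
   `split_gap_factor` × the standard deviation of merge heights inside the
   branch.  On homogeneous Gaussian blobs this gap/spread ratio stays near
   1 while genuine substructure (including elongated continua) reaches ~10,
   so the default factor 3 separates the regimes with margin; it is exposed
   in the API together with the minimum cluster size (default 20).  Branches
   below the minimum size are not clusters; their cells are rescued to the
   nearest cluster centroid.
7. **Markers** — per-gene Welch two-sample comparisons for every ordered
   cluster pair on log-expression; per focal cluster, genes with positive
   fold-change ranked by p, and the cluster's reported set is the union of
   the top 10 per pairwise comparison.  This is an unmoderated linear-model
   contrast; empirical-Bayes variance moderation is a known omission.
8. **Reference annotation** — control cells of each cluster are summed into
   pseudo-bulk profiles; a two-component Gaussian mixture on pooled nonzero
   log2 CPM defines an expressed/not-expressed threshold at the point of
   equal posterior (fallback to the pooled median, with a warning, if the
   two components sit closer than 0.5 log2 units); each cluster's expressed
   set is tested against each reference type's expressed set with a
   one-sided (enrichment) Fisher exact test over the shared gene universe;
   BH correction runs across references within a cluster, and up to ten
   significant references are reported sorted by decreasing odds ratio
   (infinite odds ratios — empty off-diagonals — sort first, ties by p).
9. **SOM / MST topology** — a batch self-organizing map (9×9 rectangular
   grid) on the first 30 denoised PCs: the codebook is initialized from
   seeded random data points, a Gaussian neighborhood shrinks linearly from
   the grid radius to 1 over 10 epochs, and a final best-matching-unit-only
   pass sets each node to the mean of its assigned cells so quantization is
   exact at convergence (a plain σ = 1 endpoint leaves codebook vectors
   blended with their grid neighbors).  The minimal spanning tree over
   Euclidean codebook distances orders the nodes.  Per-node condition
   composition is reported as the normalized cKO share
   (n_cKO/N_cKO) / (n_cKO/N_cKO + n_ctrl/N_ctrl), so unequal total cell
   numbers per condition do not bias every node toward the larger group.
10. **Differential density** — per condition, a product-Gaussian KDE on a
    shared 100×100 grid spanning the union data range ±5%; per-axis
    bandwidth 1.06·min(sd, IQR/1.34)·n^(−1/5).  The grid density is
    renormalized to trapezoid-integrate to exactly 1 (kernel tails of
    boundary points would otherwise leak mass off-grid).  The differential
    map is log2(cKO density + 10⁻³) − log2(control density + 10⁻³); the
    log-difference form makes condition-swap antisymmetry bit-exact.
11. **Pseudo-bulk DE** — UMI counts summed per (sample, cluster) when ≥ 20
    cells can be aggregated; a cluster is analyzable with ≥ 3 replicates
    per condition.  Genes are kept when CPM > 1 in ≥ 3 aggregates and
    detected in ≥ 20 single cells of the analyzed cluster.  TMM factors:
    reference column by upper-quartile CPM closest to the mean; M/A on
    genes nonzero in both; two-sided trimming of 30% (M) and 5% (A) by
    ranks; inverse-asymptotic-variance weighted mean of M; geometric mean
    scaled to 1.  Each gene is fitted with an NB GLM (log link, intercept +
    condition, offset = log(library × TMM factor)) by IRLS vectorized
    across genes, and tested with a likelihood-ratio test against the
    intercept-only model (χ², 1 df), BH-corrected within the cluster; DE ⇔
    q < 0.05.  Effective (TMM-adjusted) library sizes are the default
    offsets.
12. **Gene-set tests** — camera-style competitive test on per-gene signed
    z = sign(log2FC)·√LRT: for a set of m of G tested genes, δ = mean z
    inside − mean z outside, sd² = (1/m + 1/(G−m))·σ̂²_z·VIF with
    VIF = 1 + (m−1)ρ, ρ = 0.01; two-sided normal p, BH across sets within
    cluster; only sets with more than ten tested genes.  σ̂²_z is the
    empirical variance of all tested z-statistics, which keeps the test
    calibrated when the χ²-derived z-scores are over- or under-dispersed.
13. **Transfer ratios** — for competitive adoptive transfers, IR =
    donor/competitor counts pre-transfer; recovered ratios are divided by
    IR.  Empty competitor gates yield an explicit NaN rather than 0 or ∞.

## Dispersion estimation

The common per-cluster NB dispersion maximizes the aggregate Cox–Reid
adjusted profile likelihood (1-D bounded search on log φ over
[10⁻⁶, 5]; per-gene means re-fitted by IRLS at every candidate φ; the
adjustment subtracts ½·log det(XᵀWX) per gene).  The unadjusted profile MLE
is biased low when each gene spends 2 of its 8 degrees of freedom on mean
parameters — measured 0.071 for a true φ = 0.1 — which inflates the LRT
type-I error to ~9%; with the adjustment the estimate is ~0.0985 and the
measured type-I error ~4.5–5.3% at nominal 5%.  Tagwise (empirical-Bayes
shrunken) dispersions are not implemented; with ≥ 3 pseudo-bulk replicates
per condition a common dispersion is a defensible simplification, and the
null calibration is verified by simulation in the test suite.

A power note: with 4-vs-4 replicates, mean count 50 and φ = 0.1, the
standard error of the log fold-change estimate is
√(2·(1/50 + 0.1)/4) ≈ 0.245 natural-log units, so even an oracle two-sided
test at α = 0.05 detects a 2-fold change with probability
Φ(ln2/0.245 − 1.96) ≈ 0.81; at BH FDR < 5% among mostly-null genes the
realized sensitivity is necessarily lower.  Detecting 2-fold changes with
high confidence at these depths requires more replicates or deeper
aggregates.

## Synthetic data generator

`simulate_waterfall` emulates the study design: 8 samples (4 control, 4
cKO), 400 cells per sample, 2,000 genes, five trajectory-ordered
populations from Ly6C-high monocytes to MHCII-high macrophages.  Counts are
gamma-Poisson (NB) with variance μ + φμ²; per-gene dispersions follow a
decreasing trend in the mean over 0.05–0.5 (typical of UMI data); cell size
factors are lognormal (σ = 0.3) around an expected library of 5,000 UMIs.
Expression structure: per-population marker modules (15 genes, 8-fold on,
effectively off elsewhere, intermediate in trajectory neighbors), published
marker symbols for readability (Ccr2/Ly6c2/Cd14 for monocytes;
Cx3cr1/Adgre1/Cd81/Cd74/Cd72/Cd63/EYFP for macrophages), 30% "gradient"
genes whose log-means vary linearly along the trajectory (the continuum
that makes the waterfall a trajectory rather than islands), 25% silent
genes, and flat housekeeping for the rest — silent/off states give the
clearly bimodal pseudo-bulk expression distribution the binarization stage
requires.  Planted effects: a 12-gene apoptosis module
(Bcl2l11, Casp3, Casp8, Osm, Fos, Tnf, Fas, Trp53, Bax, Bak1, Jun, Gadd45a)
is 2-fold up in cKO monocytes, and the cKO composition is shifted toward
the early-monocyte population (0.28 vs 0.14) and away from the mature
MHCII-high macrophages (0.10 vs 0.26).  QC plants: 5% of cells fail QC
(half tiny libraries ~300 UMIs, half ~15% mitochondrial fraction) and 1%
carry hemoglobin UMIs.  All effect sizes and compositions are invented
defaults chosen to be detectable at the design's sample sizes; none is a
published measurement.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, zero-inflation beyond NB sampling, gene–gene correlation within
cells beyond the population structure, and realistic dropout–depth
coupling.  Passing tests therefore demonstrate that the implementation
recovers structure it is designed to see under NB sampling noise — not
robustness to the full artifact spectrum of real droplet data.

`simulate_reference` provides bulk-style profiles for five cell types
(monocyte, macrophage, DC, lymphoid, stromal) on the same gene universe;
the monocyte/macrophage profiles reuse the population means (so matched
types share their expressed markers), and the other types switch the
myeloid modules off and carry 30 own marker genes.  Reference profiles are
binarized with the same mixture-threshold rule as pseudo-bulk queries.

## Numerical and degenerate-input choices

- MTX I/O is plain-text MatrixMarket (optionally gzipped) and round-trips
  integer counts exactly.
- Loess uses statsmodels' tricube local linear smoother with 3
  robustifying iterations; fitted variances are clamped at 0.
- The deconvolution solver raises (suggesting larger pools) if any factor
  is non-positive rather than silently clipping.
- IRLS clamps linear predictors and coefficients at ±30 so genes with an
  all-zero condition converge to the boundary with the correct fold-change
  sign; convergence is judged on fitted means, not coefficients.
- `bh_fdr` ignores NaN p-values (non-converged genes) and preserves their
  NaN in the output.
- The Gaussian-mixture binarization seeds scikit-learn's initialization,
  making thresholds reproducible and shift-equivariant.
- Ward linkage and the MST inherit determinism from scipy; the SOM and
  t-SNE take explicit seeds; the pipeline fans a single global seed out to
  per-stage child seeds so stages can be rerun independently.

## Problem sizes used in verification

The test suite and acceptance script run the full design (8 × 400 cells,
2,000 genes) for end-to-end checks — ten seeds for the recovery battery —
and reduced designs (100–200 cells/sample, 300–1,500 genes) for unit-level
properties; null-calibration simulations use 2,000 genes at 4-vs-4
replicates.  These sizes were chosen so every statistical check retains
clear resolution (binomial margins on rejection rates, <5% relative error
bounds on recovery) while a complete run stays fast on one CPU.

## Known limitations

- Marker tests are unmoderated Welch comparisons; small clusters give noisy
  fold-change rankings.
- The dynamic cut is a simplified gap rule, not the full hybrid
  dendrogram-cut algorithm; its `split_gap_factor` matters on data with
  weak separations and is deliberately exposed.
- Common (not tagwise) NB dispersion per cluster.
- The camera test uses a normal approximation with an empirical background
  variance rather than ranked residual t-statistics.
- No doublet detection, adaptive QC thresholds, or spike-in normalization.
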