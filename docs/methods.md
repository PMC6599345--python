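# Methods

This note documents the models, parameter choices and numerical
decisions behind `dcfate`, in the order the pipeline runs them.

## 1. Quality control and normalization (`dcfate.qc`)

Cells are kept when they satisfy all of: total reads assigned to
endogenous genes ≥ 100,000; mitochondrial read fraction < 0.30 (strict);
detected genes (count > 0) strictly > 1000. Spike-in rows are excluded
from all three statistics: they are exogenous and their yield reflects
the dilution, not cell quality. Housekeeping and cell-cycle detection
fractions are computed for reporting only and never gate a cell.

Size factors are median-of-ratios: for cell *j*,
s<sub>j</sub> = median<sub>g∈R</sub> ( c<sub>gj</sub> / (∏<sub>k</sub> c<sub>gk</sub>)<sup>1/n</sup> ),
where the reference set *R* is the genes with a nonzero count in every
cell. Under heavy dropout *R* can be empty; the estimator then falls
back to total counts scaled to geometric mean one (logged as a warning).
Normalized values are log₂(c/s + 1), so zeros map to zero and
`NormalizedMatrix.linear()` recovers c/s exactly.

## 2. Technical-noise model and variable genes (`dcfate.hvg`)

Spike-in CV² against mean follows CV²(μ) = a₁/μ + α₀: a Poisson counting
term plus an amplification/efficiency floor. The fit is a gamma-family
GLM with identity link (the sampling noise of a CV² estimate scales with
its mean) on size-factor-normalized *linear* counts — not log values,
because the law is stated for normalized counts. Spike-ins below the
0.4 mean quantile are excluded so the 1/μ arm does not dominate;
coefficients are clipped at zero (flagged). If the GLM fails to converge
the fit falls back to least squares. At least 20 usable spike-ins and at
least a two-fold spread of spike-in means are required (the two
regressors are otherwise collinear).

The biological-variability test compares each gene's CV² to the null
CV²₀(μ) = a₁/μ + α₀ + cv²_bio with cv_bio = 0.5, via
T = (m−1)·CV²/CV²₀ ~ χ²(m−1). The additive form of the null is a
simplification (the exact small-sample null has cross terms between
technical and biological variance); its type-I error is verified by
simulation in the test suite (≈0.1% at a nominal 10% FDR — conservative).
Genes with zero mean get NaN p-values and are excluded from the BH
multiplicity count. Selection additionally requires detection in ≥ 10
cells (exposed as config; 30 is the other documented choice).

## 3. Dropout model and cell–cell distances (`dcfate.embed`)

Dropout is treated as a per-cell detection process: for cell *c*,
P(detected | g) = logistic(β₀<sub>c</sub> + β₁<sub>c</sub>·x<sub>g</sub>), where
x<sub>g</sub> is the log₂ *detected-cell* mean of gene g (the mean over cells
with a nonzero count). That covariate is used instead of the plain
pooled mean because dropout removes whole observations rather than
shrinking them, so the detected-cell mean is nearly unbiased for the
true magnitude while the plain mean is compressed exactly where the
model needs leverage. Slopes are clipped at zero with a warning (a
negative detection-vs-abundance slope indicates a pathological cell);
cells with constant detection are flagged degenerate and their
probabilities clamped to [0.01, 0.99].

The dropout-weighted distance between cells x and y is
1 − weighted Pearson correlation of log₂ expression with gene weight
v<sub>x</sub>(g)·v<sub>y</sub>(g), where v<sub>c</sub>(g) = 1 if detected and
1 − P<sub>c</sub>(detect | g) otherwise: a zero where the cell usually detects
transcripts of that magnitude is a credible biological zero and keeps
weight, a zero in the dropout regime contributes almost nothing. With no
zeros the distance reduces elementwise to 1 − Pearson (tested to 1e-12).

Classical (Torgerson) MDS double-centers −D²/2 and takes the top-k
eigenpairs. Dimensions with |eigenvalue| ≈ 0 give exact zero coordinates
(an all-zero distance matrix is embeddable at the origin); requesting
dimensions beyond the positive spectrum while genuinely negative
eigenvalues exist is an error, and truncated negative eigenvalues are
logged. Tests compare MDS output through Procrustes alignment only —
sign and rotation are not identified.

t-SNE is scikit-learn's Barnes–Hut implementation on the precomputed
distance matrix (perplexity 20, theta 0.1, random init, fixed seed);
k-means is k-means++/Lloyd, best of 50 restarts, deterministic per seed.
Clustering agreement is the *adjusted* Rand index (the chance-corrected
form; plain Rand is available behind a flag).

## 4. Differential expression (`dcfate.diffexpr`)

Bulk two-group DE is a per-gene Welch t-test on log₂ normalized values
with BH correction; genes constant in both groups get p = 1. A count
GLM would be the more powerful choice at n = 3, but the fold-change
threshold (|log₂FC| > 1) dominates the selection and the t-test keeps
the statistic exactly auditable.

Single-cell two-group DE is a Wilcoxon rank-sum test reported as a
signed Z (direction of group 2 vs group 1), with tie correction and a
continuity correction; when both groups have ≤ 10 observations and the
data are tie-free the p-value comes from exact enumeration of the U
null distribution. Top-k extraction ranks by |Z| with ties broken by
gene identifier.

The three-population signature is one-way ANOVA (BH on the F-test p)
plus Tukey HSD (studentized-range distribution, Tukey–Kramer standard
errors) for the three pairwise contrasts; a gene is selected when
q < 0.05 and at least one pair exceeds the fold-change cut. Gene
clustering is agglomerative Ward linkage on 1 − Spearman correlation
between gene expression profiles.

## 5. Master-regulator selection (`dcfate.mrtf`)

Regulon enrichment is a one-sided hypergeometric upper tail computed
within the universe of genes actually tested for DE (the only universe
the pipeline can certify), with target sets intersected with the
universe first. The combined score is −ln(p)·log₂(OR) with a Haldane
0.5 correction on the odds ratio; only its sign is consumed downstream
(enrichment vs depletion), matching how the original combined-score
heuristic is used. Selection reasons: (a) strict bulk DE
(q < 0.05, |log₂FC| > 1) or (b) regulon enrichment (BH q < 0.05 —
a defaulted choice, the enrichment-significance threshold being
otherwise unspecified) plus marginal DE (p < 0.05, same fold-change
cut). A TF meeting both is reported as "a".

## 6. Fate analysis (`dcfate.commitment`)

Subpopulation assignment embeds **all** cells by t-SNE on the
1 − Spearman distance over the MR-TF expression panel, then k-means
(k = 2) on the precursor cells' coordinates, with the mature cells
anchoring the map. Each precursor cluster is named after a mature type
by the *bijective* pairing of cluster centroids to mature-type median
coordinates that minimizes the total distance. (A greedy
nearest-type rule fails routinely: precursors sit between the two
mature blobs, so both clusters are often nearest the same type even
when their relative affinities are clear. The optimal pairing uses the
same information and is always a bijection; an exact tie is an error.)

The dose-ratio statistic is log₂((a + 1)/(b + 1)) per cell on the
normalized linear scale — pseudocount 1 matching the global log₂(x+1)
convention — with two-sided Wilcoxon rank-sum tests and rank AUCs for
the ratio and each anchor alone. Swapping the anchors negates the
ratios and maps AUC to 1 − AUC (tested).

Bimodality is operationalized as ΔBIC = BIC(1-component) −
BIC(2-component Gaussian mixture; EM, 10 restarts, fixed seed); two
modes are called when ΔBIC > 0 and the minor component holds ≥ 10% of
the mass. Calibration (≥ 90% one-mode calls on unimodal draws, 100%
two-mode calls at 6σ separation) is part of the test suite.

The resampling null samples gene sets of the observed size without
replacement from endogenous genes with mean normalized count above a
floor, re-runs 1 − Spearman → 2-D MDS → k-means for the reference
cells each round, and records the ARI against the reference labels.
The empirical p uses the add-one correction (1 + #{null ≥ obs})/(rounds + 1),
so it is never exactly zero. Default 3000 rounds; the acceptance
checks run 300 rounds at 10 replicate studies, which bounds the
resolvable p at ~3·10⁻³ per study — sufficient for a 95th-percentile
exceedance test.

## 7. The synthetic-data generator (`dcfate.simulate`)

The generator produces the exact statistical structure the pipeline
assumes, with ground truth. Defaults define the package's study
conditions:

* **Populations**: 100 pre-cDC, 50 cDC1, 50 cDC2 (the 2:1:1 mixing
  design), plus 6 dead-cell outliers (depth ÷ 20, mitochondrial
  fraction ≈ 0.5); precursor fates split 50:50 (the true proportion
  being unquantified, this is the symmetric default). Three batches
  mimic the mixing design (cDCs only / precursors only / 2:1:1
  mixture) with depth multipliers 1.0/1.15/0.85.
* **Counts**: per-gene log₂ baseline ~ N(4.0, 2.8²) (median ≈ 16
  normalized counts, a long high-expression tail carries most reads,
  ≈ 250k reads per healthy cell); Gamma–Poisson with extra-Poisson
  dispersion 0.1; per-cell capture efficiency (lognormal, σ = 0.25 log₂)
  shared by genes and spike-ins, RNA-content factor (σ = 0.10 log₂) on
  genes only.
* **Dropout**: Bernoulli detection, logistic in the per-cell log₂ mean,
  intercept −10, slope 3. The steep curve concentrates dropout below
  ~16 counts and yields ≈ 40–44% zeros overall. A shallower curve
  reaching 50–60% zeros was rejected: it inflates CV² across a wide
  mid-expression band, and because the spike-ins (which calibrate the
  null) are modeled dropout-free, more than half the transcriptome then
  tests as "variable" — a regime in which none of the study's gene-set
  contrasts is meaningful.
* **Spike-ins**: 92 sequences, log-uniform abundance over ~3 decades,
  Gamma–Poisson tuned so normalized counts satisfy
  CV² = a₁/μ + α₀ with a₁ = 1.0, α₀ = 0.05 (a₁ ≥ 1 is enforced: the
  Poisson counting floor is not reducible for integer counts), no
  biological factor and no dropout.
* **Planted structure**: 150 cDC1-vs-cDC2 signature genes (|log₂FC| = 2)
  that also fluctuate fate-*independently* in precursors (biological
  CV 1.3), plus 200 pure high-variability genes; 300 pre-vs-cDC
  signature genes (|log₂FC| = 2); a latent per-cell state factor
  (activation/maturation continuum, N(0,1)) loading on 300 background
  genes with N(0, 0.8²) log₂ loadings in *all* populations. The state
  program is essential: without structured fate-independent
  heterogeneity, centroid methods on ~100 cells detect arbitrarily
  weak but consistent signals (two informative genes out of 400 were
  enough for a perfect split), and none of the study's negative
  results can exist. Fate-program genes are moderately expressed
  (log₂ mean ~ N(3.2, 0.8²)), below the housekeeping-dominated
  high-mean pool that the resampling null draws from — the biological
  claim being that regulatory genes, not bulk housekeeping output,
  carry the fate signal.
* **Master regulators**: 16 TFs. The two anchors (named IRF8/IRF4)
  at log₂ base 6 follow the combinatorial-dose model: shared activity
  u ~ N(0, 3²) added to both log₂ doses, fate shifting their
  difference by ±δ/2 with δ = 2, plus independent N(0, 0.3²) dose
  noise — so the log ratio separates the fates while each marginal
  overlaps (σ_u ≫ δ). The 14 other MR TFs get mature |log₂FC| ~
  U(1.2, 2.5) with random sign, attenuated ×0.8 in precursors with
  N(0, 0.5²) dose noise (the commitment program is only partially
  established before terminal differentiation). 24 decoy TFs carry no
  fate information. The generated regulon file (GMT) gives each MR TF
  40% of the signature genes plus a few background genes; decoys get
  size-matched random sets.
* **Bulk**: three replicates per population, negative binomial around
  the population's expected expression profile at 20× depth with
  replicate-level dispersion 0.01 (≈ 10% CV between sorted-population
  replicates).

What the generator does **not** emulate: real gene-length/GC biases,
UMI structure, doublets, ambient RNA, realistic gene symbols, and
correlated regulon activity beyond the single state factor. Passing
tests therefore demonstrate the pipeline's correctness and calibration
under its own modeling assumptions, not performance on any real
dataset.

## 8. Problem sizes and determinism

All stochastic components take explicit seeds; the same seed gives
bit-identical simulations and embeddings. The standard test and
acceptance runs use 2000 genes + 92 spike-ins and ~200 cells per study,
10 replicate studies for the comparative claims and 20 for the
calibration claims, and 300-round resampling nulls — sizes chosen so a
full from-scratch verification completes in minutes on a single core
while keeping every Monte-Carlo margin comfortable.
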