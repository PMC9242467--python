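# Methods

This note documents the statistical model behind `celltrait`, the
defaults that matter, the synthetic-data generator and what it does and
does not emulate, and the numerical and design choices made where the
method leaves room.

## Gene-level association statistics

**Common variants.** For a gene with K common SNPs the test statistic
is the quadratic form Q_c = ẑᵀR⁻¹ẑ where ẑ are the SNP z-scores
(ẑ_j = β̂_j/σ̂_j) and R the SNP correlation (LD) matrix. Under the null
of no association, ẑ is approximately N(0, R) and Q_c ~ χ²_K. The
quadratic form is evaluated by a Cholesky solve, never by an explicit
inverse, and p-values are carried on the log scale so genes with
p < 1e-300 remain ordered.

**LD regularization (POET).** R is estimated from a genotype reference
panel of a few hundred individuals; with K up to 200 SNPs the sample
correlation matrix is ill-conditioned or rank-deficient, and its
underestimated small eigenvalues would inflate Q_c. The POET estimator
eigendecomposes R, keeps the top H spiked components, and applies
entrywise adaptive soft-thresholding to the residual off-diagonals at
τ = c·√(log K / n), leaving the diagonal untouched. H defaults to
"auto": the arg-max of consecutive eigenvalue ratios λ_j/λ_{j+1} over
the leading half of the spectrum, capped at 10. The constant c is the
smallest value on the grid {0.1, 0.2, …, 2.0} whose result has minimum
eigenvalue above 1e-4; the chosen H, c and rule are recorded in the
matrix metadata. Soft-thresholding was chosen over hard thresholding
for continuity in c; POET's correlation-scaled adaptive threshold is an
acceptable alternative behind the same interface.

**Rare variants.** SNPs with MAF below 1% enter a burden statistic
reconstructed from summary statistics: with weights w_j = 1/σ̂_j the
score-scale statistics are U_j = w_j ẑ_j with covariance
C_jl = w_j R_jl w_l, giving z_r = wᵀẑ/√(wᵀRw) ~ N(0,1) and
Q_r = z_r² ~ χ²₁. Burden tests presume shared effect direction; with
mixed signs the numerator cancels (the simulation suite demonstrates
this) while the common-variant quadratic form retains power. A gene's
rare set is tested only when its total minor allele count
(Σ_j 2 n_j maf_j from the summary statistics) strictly exceeds 20;
otherwise the rare set is dropped and the gene falls back to the
common-variant test.

**Joint test.** The rare variants collapse into one pseudo-SNP with
z-score z_r appended to the common z-vector; Q = z*ᵀR*⁻¹z* ~ χ²_{K+1}.
The cross-correlation between common SNP j and the pseudo-SNP is
computed analytically from the POET-shrunk common+rare LD block,
(Σ_l w_l R_jl)/√(wᵀR_rr w) — exactly the correlation of SNP j with the
w-weighted standardized rare-dosage sum, so R* is a congruence
transform of a positive definite matrix and inherits positive
definiteness, and the denominator matches the burden statistic's.
Synthesizing the collapsed dosage column and shrinking the (K+1)
sample correlation directly is supported (`method="pseudo-column"`)
and agrees; the analytic route is the default because it is exactly
self-consistent.

## Gene-gene correlation

Genes within a few hundred kilobases share cis-SNPs and LD, making
their chi-square statistics dependent — exactly the dependence the
enrichment regression must whiten. Under joint normality of the SNP
z-scores,

    ρ_st = cor(Q_s, Q_t) = ‖R_s^{-1/2} R_st R_t^{-1/2}‖²_F / √(K_s K_t),

the squared Frobenius norm of the whitened cross-LD block. The same
number is the sum of squared entries of the off-diagonal Cholesky
block of the jointly whitened matrix [[I, C], [Cᵀ, I]]; that route is
retained as an equivalence check in the tests, while production uses
symmetric eigendecompositions for the matrix square roots. In the
1-SNP limit ρ = r² exactly; the general formula is validated against
Monte-Carlo simulation of the quadratic forms (5×10⁵ draws per
configuration, agreement within 3 Monte-Carlo standard errors).

ρ is computed only for within-chromosome pairs with index separation
≤ d−1 (default d = 10, so an interior gene has 18 correlated
neighbors) and body-to-body distance ≤ 5 Mb; all other entries of the
sparse matrix P are exactly zero. Each eligible pair is evaluated
directly from its own two-gene joint POET-shrunk block rather than
once per overlapping window — overlapping windows would yield multiple
estimates for the same pair, while the direct evaluation gives the
single well-defined value. Genes with overlapping windows share SNPs;
the shared SNPs appear in both partitions and push ρ toward 1, which
is the intended behavior. If assembled P is not positive definite it
is repaired by diagonal shrinkage P ← (1−δ)P + δI with the smallest
δ ∈ {0.01, 0.02, …} restoring a positive spectrum; δ is recorded in
the output metadata (at the package's scales δ = 0 throughout).

## Cell-type enrichment GLS

The outcome is Y_g = Q_g/df_g with df_g the degrees of freedom of the
statistic actually computed (K for common-only, K+1 joint, 1 rare-
only); under the null Y_g has mean 1 and variance 2/df_g. The model

    Y = γ₀ + E_c γ_c + A γ_A + ε,   ε ~ N(0, σ²W),   W = D P Dᵀ

uses D = diag(√(2/df_g)) so that diag(W) equals the null variance of
Y; the square root is forced by that variance identity. E_c is the
cell type's log2(RPKM+1) (or log2(TPM+1)) expression and A the
per-gene average over cell types, controlling baseline expression.
Fitting whitens by the Cholesky factor of W and runs OLS on the
whitened system; σ² is estimated on N−3 residual df, and the one-sided
test of γ_c > 0 uses a Student t reference with N−3 df (the reference
distribution is asymptotically equivalent to normal; t was chosen to
be conservative at small N). One fit per cell type, each with its own
E_c and the shared A; the per-scan Bonferroni threshold is 0.05/T.
Genes missing from any of the three sources (statistics, expression,
P) are dropped listwise with a logged count.

**Influence.** For a significant cell type, the effect of each gene on
γ̂_c is measured by exact leave-one-out: DFBETA_g = γ̂_c − γ̂_c(g) and
DFBETAS_g = DFBETA_g / se(γ̂_c(g)). Removing a gene from a GLS removes
a row *and* a column of W, so the downdate works on the precision
scale: with Ω = W⁻¹, the submatrix identity
(W_{-g,-g})⁻¹ = Ω_{-g,-g} − Ω_{-g,g}Ω_{g,-g}/Ω_{gg} turns each
leave-one-out fit into rank-one updates of XᵀΩX, XᵀΩY and YᵀΩY. The
downdate is algebraically exact and is verified against brute-force
refits to 1e-8. The influential set uses the size-adjusted cutoff
|DFBETAS| ≥ 2/√N; signed values are reported so users can restrict to
positive drivers.

**Overlap testing.** Agreement between two significant-gene call sets
is scored by the hypergeometric upper tail P(X > q) with m/n
significant/insignificant genes in set A and k significant in set B —
the strictly-greater tail, verified against exhaustive enumeration.

## Input processing

Summary statistics are read from delimited text with a configurable
column map; rows with invalid fields are dropped and counted,
autosomes only. Alleles are harmonized against the reference panel:
SNPs absent from the panel are removed, swapped effect/other alleles
flip the sign of β and z, strand-ambiguous (A/T, C/G) SNPs are dropped
(panel and GWAS are assumed to share a genome build; no liftover). The
MHC region defaults to chr6:25–35 Mb (GRCh37 convention, configurable)
and is excluded for its LD complexity. Gene windows extend 10 kb
upstream and 1.5 kb downstream of the gene body, strand-aware, with
unknown strand treated as '+'; a SNP in overlapping windows is
assigned to every covering gene. The common/rare MAF boundary is 1%
with maf ≥ cutoff classed common. LD pruning is greedy within sliding
windows of 50 SNPs advanced by 5: when r² > 0.8 the later-position SNP
is removed; if more than 200 SNPs survive, pruning repeats at
thresholds 0.7, 0.6, …, 0.1, and any residual excess is resolved by
keeping the largest-MAF SNPs (a phenotype-agnostic tie-break). The
window/step and second-round mechanics are this package's documented
dialect of the standard pairwise pruning procedure.

Cell-level counts pool per cell type (RPKM with the pooled library
size of the cell type and gene length in bp; pseudo-count 1 inside
log2). Highly variable genes (default top 8,000) are ranked by
binned-normalized dispersion on log-normalized counts via scanpy's
Seurat-style recipe. Bulk tissue matrices are filtered by a tissue
specificity score — the z-score of a gene's expression across tissues
(population SD), keeping genes whose maximum score exceeds 5; the
score formula and threshold are configurable, as the definition is a
documented design choice. Cell-type markers use a one-sided Wilcoxon
rank-sum test with Bonferroni correction (test and correction are
likewise package choices).

## Synthetic-data generator

Genotypes follow a latent-Gaussian threshold model: per gene, each of
two independent haplotypes draws a latent AR(1) vector (adjacent
correlation `latent_rho`, default 0.6) and carries the minor allele
above the 1−MAF quantile. Dosages are 0/1/2 with Hardy–Weinberg
marginals, and the implied LD is available in closed form through the
bivariate normal orthant probability (`dosage_corr`), giving the test
suite an analytic oracle. MAFs are uniform on (0.05, 0.5) by default.
Summary statistics come from per-SNP univariate logistic regressions
(vectorized IRLS, 25-iteration cap, clipped linear predictors as a
separation guard) — Wald β, SE, z and two-sided p, the same path a
GWAS would take. The null design draws Bernoulli(θ) phenotypes
(θ ∈ {0.1, 0.2, 0.5} in the study grid, default 0.2) on a reference
panel of 500 individuals bootstrap-resampled to the analysis size; the
power design plants log-odds effects in a causal fraction
(grid {5%, 20%, 50%}, default 20%) of a gene's SNPs with equal or
mixed signs and collects balanced case/control samples by oversampling
a fresh pool and subsetting to 50/50. Dosages enter the liability
centered — an implicit intercept pinning baseline prevalence at 50% so
balance is reachable for any causal configuration. Power is read at
α = 1e-6 by default.

The end-to-end fixture (200 genes × 10 SNPs, 500-individual panel,
GWAS of 2,000 balanced cases/controls, 8 cell types) embeds its truth:
20% of genes are causal (40% of their SNPs at |β| = 0.25), and cell
type 0's expression — baseline N(4, 1.5²) truncated at 0 on the log2
scale — is raised by 1.5 log2 units exactly for causal genes. The GWAS
cohort is synthesized fresh from the same population model rather than
resampled from the panel: resampling a small panel into a larger
cohort leaks the polygenic signal into non-causal genes through finite-
panel spurious LD (≈1/√n_panel per SNP pair, summed over all causal
SNPs), which real studies do not exhibit because cohort and reference
panel are independent samples. With a fresh cohort, non-causal genes
are exactly null and the panel plays its real role of an external LD
reference.

What the generator does not emulate: real LD block structure beyond
AR(1) decay (no long-range LD, no MHC-like regions), allele-frequency
spectra, genotyping error and imputation noise, population
stratification, overlapping gene windows (fixture genes are spaced
100 kb apart), library-size and dropout artifacts of real scRNA-seq,
or correlated expression across cell types. Passing tests therefore
demonstrate the statistical machinery — calibration, whitening,
influence, recovery of an embedded signal — under the stated model,
not robustness to those real-data complications.

## Verification problem sizes

The verification suite (`tests/test_acceptance.py`,
`scripts/acceptance.py`) runs at desk scale, chosen so the whole suite
completes in minutes on one CPU while keeping Monte-Carlo error well
below the tolerances checked: the null-calibration design uses 20
genes of 10–40 SNPs, a 500-individual panel resampled to 1,000, θ=0.2
and 500 replicates (10,000 gene p-values; the type I error at 0.05 is
checked against the exact binomial 99% interval); the gene-pair
correlation oracle uses 20 random configurations with K ≤ 5 and 5×10⁵
draws each; GLS recovery uses N = 2,000 genes with banded P and 200
replicates at γ_c = 0.5; the influence downdate is checked on 50
random 20-gene regressions; the permutation null uses 200 expression
permutations of the standard fixture; and the end-to-end check runs
the full pipeline on 100 fixture seeds, requiring the embedded cell
type to rank first in at least 95. Within the bootstrap null design,
duplicated panel rows make the gene-level test very slightly
conservative (empirical type I error ≈0.045–0.05 at nominal 0.05, at
the edge of the binomial interval); with independently drawn cohorts
of the same size the test is calibrated exactly (≈0.050), which is the
regime the fixture emulates.

## Known limitations

Cross-chromosome and beyond-window gene correlations are fixed at
zero by construction. The burden weights 1/σ̂_j approximate the score
variance and inherit any SE miscalibration of the source GWAS. The
joint test requires the rare and common variants to be present in the
reference panel. The GLS tests cell types one at a time; conditional
multi-cell-type modeling, heritability partitioning and pathway
enrichment of influential genes are out of scope, as are genome-build
liftover and imputation.
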