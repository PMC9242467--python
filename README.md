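# celltrait

Gene-level association testing from GWAS summary statistics and
prioritization of trait-relevant cell types by integrating those
statistics with cell-type-resolved expression.

## The problem

Genome-wide association studies report per-SNP effect sizes β̂_j,
standard errors σ̂_j, and z-scores ẑ_j = β̂_j/σ̂_j, but the biology acts
through genes and specific cell types. `celltrait` answers two linked
questions for analysts who have only summary statistics, a genotype
reference panel, and an expression matrix:

1. **Which genes are associated?** For the K common variants in a gene
   window, the chi-square statistic

       Q_c = ẑᵀ R⁻¹ ẑ  ~  χ²_K   under H₀,

   where R is the SNP LD (Pearson correlation) matrix estimated from
   the reference panel and regularized with POET shrinkage (top spiked
   eigencomponents retained, residual off-diagonals soft-thresholded
   until the matrix is positive definite). Rare variants (MAF < 1%,
   tested only when the gene's minor-allele count exceeds 20) enter a
   burden statistic reconstructed from z-scores,
   Q_r = (wᵀẑ)²/(wᵀRw) ~ χ²₁ with weights w_j = 1/σ̂_j, and can join the
   common variants as one collapsed pseudo-SNP in a joint χ²_{K+1} test.

2. **Which cell types are relevant?** With Y_g = Q_g/df_g as outcome
   (mean 1, variance 2/df_g under the null), each cell type c is tested
   with a generalized least squares regression

       Y = γ₀ + E_c γ_c + A γ_A + ε,   ε ~ N(0, σ²W),  W = D P Dᵀ,

   where E_c is the cell type's log2 expression, A the per-gene average
   across cell types, D = diag(√(2/df_g)), and P the gene-gene
   correlation matrix of the chi-square statistics, computed
   analytically from cross-gene LD within a sliding window of d = 10
   genes (and 5 Mb). The one-sided test of γ_c > 0 asks whether GWAS
   signal concentrates in genes the cell type expresses highly.
   Leave-one-out DFBETAS flag the genes that drive a significant
   enrichment, and hypergeometric tests compare influential-gene sets
   with other call sets.

A first-class simulation module generates LD-structured genotype
panels (latent AR(1) threshold model with analytically known LD),
per-SNP logistic-regression summary statistics under null and
alternative designs, and complete end-to-end fixtures with one
embedded trait-relevant cell type.

## Worked example

```bash
python examples/03_cell_type_enrichment.py
```

generates a miniature study (200 genes × 10 SNPs, a GWAS of 2,000
balanced cases/controls, 8 cell types with `celltype0` enriched) and
prints, among other lines:

```
truth: enriched cell type = celltype0, 40 causal genes of 200

cell-type enrichment (one-sided test of gamma_c > 0):
cell_type   gamma_c       se         t  p_one_sided  ...  bonferroni_sig
celltype0  0.257246 0.046563  5.524683 5.179916e-08  ...            True
celltype3  0.093473 0.049437  1.890752 3.006260e-02  ...           False
...

influential genes for celltype0 (|DFBETAS| >= 0.141): 21
of which truly causal: 13
```

`gamma_c` is the GLS slope of the df-adjusted gene statistics on
cell-type-specific expression; only the truly enriched cell type is
Bonferroni-significant, and the influential-gene list recovers mostly
truly causal genes. The other examples walk through gene-level tests
(`01`), the gene-gene correlation matrix (`02`), expression processing
(`04`), and the null/power simulation designs (`05`).

The same analyses are available from the shell:

```bash
celltrait gene-test --sumstats ss.tsv --panel panel --genes genes.bed \
    --mode joint --out genestats.tsv --genecorr-out genecorr.tsv
celltrait enrich --genestats genestats.tsv --genecorr genecorr.tsv \
    --expr expression.tsv --out enrichment.tsv
```

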