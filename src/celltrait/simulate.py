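"""Synthetic genotype panels, GWAS scans, and end-to-end fixtures.

Genotypes follow a latent-Gaussian threshold model: per gene, each
haplotype draws a latent AR(1) Gaussian vector (correlation
``latent_rho`` between adjacent SNPs) and carries the minor allele
where the latent value exceeds the 1-MAF quantile, so dosages are
0/1/2 with Hardy-Weinberg marginals and analytically tractable LD
(the implied dosage correlation is available in closed form through
the bivariate normal orthant probability, see :func:`dosage_corr`).

SNP-level summary statistics are produced the way a GWAS would:
per-SNP univariate logistic regression (intercept + dosage) fit by
iteratively reweighted least squares with a separation guard, under a
Bernoulli(theta) null phenotype or a multi-SNP log-odds alternative
with balanced case-control sampling.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .expression import CellTypeExpression
from .gwas_io import GeneModel
from .ld_panel import GenotypePanel, LdMatrix

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Generating parameters for the synthetic study designs.

    Defaults mirror the simulation designs at desk scale: a reference
    panel of ~500 individuals resampled to larger GWAS cohorts, null
    phenotypes Y ~ Bernoulli(theta) with theta in {0.1, 0.2, 0.5}
    (default 0.2), causal proportions in {0.05, 0.20, 0.50} (default
    0.20) with per-SNP log-odds ``beta``, and power read off at
    alpha = 1e-6.
    """
    n_individuals: int = 500
    n_genes: int = 20
    n_snps_per_gene: int | tuple = (10, 40)
    latent_rho: float = 0.6
    maf_range: tuple = (0.05, 0.5)
    theta: float = 0.2
    causal_prop: float = 0.2
    beta: float = 0.2
    effect_signs: str = "same"  # {same, mixed}
    n_replicates: int = 500
    alpha: float = 1e-6
    seed: int | None = None
    gene_spacing: int = 100_000
    snp_spacing: int = 1_000
    # fixture-only parameters
    n_cell_types: int = 8
    causal_gene_prop: float = 0.2
    expr_shift: float = 1.5

    def __post_init__(self):
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        if not 0 < self.causal_prop <= 1:
            raise ValueError("causal_prop must lie in (0, 1]")
        if not 0 <= self.latent_rho < 1:
            raise ValueError("latent_rho must lie in [0, 1)")

    def rng(self) -> np.random.Generator:
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic operations")
        return np.random.default_rng(self.seed)


@dataclass
class SimResult:
    """Per-replicate gene p-values and the empirical rate they imply."""
    p_values: np.ndarray  # replicates x genes
    alpha: float
    rate: float
    mc_se: float
    per_gene_rate: np.ndarray = None

    @classmethod
    def from_pvalues(cls, p: np.ndarray, alpha: float) -> "SimResult":
        p = np.atleast_2d(p)
        hits = p < alpha
        rate = float(hits.mean())
        n = hits.size
        return cls(p, alpha, rate, float(np.sqrt(rate * (1 - rate) / n)),
                   per_gene_rate=hits.mean(axis=0))


# ---------------------------------------------------------------------------
# genotype model

def _ar1_latent(rng, n_rows: int, K: int, rho: float) -> np.ndarray:
    z = rng.standard_normal((n_rows, K))
    if rho > 0:
        out = np.empty_like(z)
        out[:, 0] = z[:, 0]
        c = np.sqrt(1 - rho ** 2)
        for k in range(1, K):
            out[:, k] = rho * out[:, k - 1] + c * z[:, k]
        return out
    return z


def dosage_corr(latent_rho: float, maf1: float, maf2: float) -> float:
    """Exact dosage correlation implied by the latent threshold model.

    With thresholds t_i at the (1 - maf_i) normal quantile and latent
    correlation r, the two haplotypes are independent, so
    cor(X_1, X_2) = (P11 - p1 p2) / sqrt(p1 q1 p2 q2) with
    P11 = P(u_1 > t_1, u_2 > t_2) under the bivariate normal.
    """
    t1, t2 = stats.norm.ppf(1 - maf1), stats.norm.ppf(1 - maf2)
    bvn = stats.multivariate_normal(mean=[0, 0],
                                    cov=[[1, latent_rho], [latent_rho, 1]])
    p11 = 1 - stats.norm.cdf(t1) - stats.norm.cdf(t2) + float(bvn.cdf([t1, t2]))
    return (p11 - maf1 * maf2) / np.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))


def true_ld(mafs, latent_rho: float) -> LdMatrix:
    """The model-implied LD matrix of one AR(1) gene block."""
    mafs = np.asarray(mafs, dtype=float)
    K = len(mafs)
    R = np.eye(K)
    for j in range(K):
        for l in range(j + 1, K):
            r = dosage_corr(latent_rho ** (l - j), mafs[j], mafs[l])
            R[j, l] = R[l, j] = r
    return LdMatrix(R, [f"s{j}" for j in range(K)], shrunk=False,
                    min_eigenvalue=float(np.linalg.eigvalsh(R)[0]))


def _synth_blocks(rng, n: int, gene_mafs: list, latent_rho: float) -> np.ndarray:
    """Fresh dosages for ``n`` individuals over the given gene blocks."""
    blocks = []
    for mafs in gene_mafs:
        K = len(mafs)
        thr = stats.norm.ppf(1 - mafs)
        hap1 = _ar1_latent(rng, n, K, latent_rho) > thr
        hap2 = _ar1_latent(rng, n, K, latent_rho) > thr
        # bool + bool would be logical OR; dosage is the allele count
        blocks.append(hap1.astype(np.float64) + hap2.astype(np.float64))
    return np.hstack(blocks)


def synth_panel(cfg: SimConfig) -> GenotypePanel:
    """Simulate an LD-structured genotype panel of AR(1) gene blocks.

    Panel metadata records the generating MAFs, the latent correlation,
    and one GeneModel per block (genes spaced far enough apart that
    their flanked windows do not overlap).
    """
    rng = cfg.rng()
    n = cfg.n_individuals
    blocks, var_rows, gene_models, gene_mafs = [], [], [], []
    pos = 1_000_000
    for g in range(cfg.n_genes):
        if isinstance(cfg.n_snps_per_gene, int):
            K = cfg.n_snps_per_gene
        else:
            lo, hi = cfg.n_snps_per_gene
            K = int(rng.integers(lo, hi + 1))
        mafs = rng.uniform(*cfg.maf_range, size=K)
        blocks.append(_synth_blocks(rng, n, [mafs], cfg.latent_rho))
        gid = f"gene{g:04d}"
        positions = pos + np.arange(K) * cfg.snp_spacing
        for j in range(K):
            var_rows.append((f"{gid}_s{j}", "1", int(positions[j]), "A", "G"))
        gene_models.append(GeneModel(gid, "1", int(positions[0]), int(positions[-1])))
        gene_mafs.append(mafs)
        pos += max((K - 1) * cfg.snp_spacing, 1) + cfg.gene_spacing
    variants = pd.DataFrame(var_rows,
                            columns=["variant_id", "chrom", "pos", "ref", "alt"])
    meta = {"latent_rho": cfg.latent_rho, "gene_models": gene_models,
            "gene_mafs": gene_mafs, "seed": cfg.seed}
    return GenotypePanel(np.hstack(blocks), variants, meta)


def resample_panel(panel: GenotypePanel, n: int, seed: int,
                   resample: bool = True) -> GenotypePanel:
    """Bootstrap individuals (rows) with replacement to size ``n``."""
    if panel.n_individuals == 0:
        raise ValueError("empty panel")
    if not resample:
        return panel
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, panel.n_individuals, size=n)
    return GenotypePanel(panel.dosages[idx], panel.variants, dict(panel.meta))


# ---------------------------------------------------------------------------
# per-SNP logistic scans

def logistic_scan(X: np.ndarray, y: np.ndarray, max_iter: int = 25,
                  tol: float = 1e-8) -> pd.DataFrame:
    """Univariate logistic regressions (intercept + dosage), one per column.

    Newton/IRLS vectorized across SNPs with a separation guard (linear
    predictors clipped, slopes capped, fixed iteration budget). Returns
    per-SNP Wald beta, se, z and the two-sided normal p-value.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("degenerate phenotype (all cases or all controls)")
    b0 = np.full(m, logit(ybar))
    b1 = np.zeros(m)
    for _ in range(max_iter):
        eta = np.clip(b0 + X * b1, -30, 30)
        mu = expit(eta)
        w = mu * (1 - mu)
        res = y[:, None] - mu
        g0 = res.sum(axis=0)
        g1 = (res * X).sum(axis=0)
        S0 = w.sum(axis=0)
        S1 = (w * X).sum(axis=0)
        S2 = (w * X * X).sum(axis=0)
        det = S0 * S2 - S1 * S1
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        db0 = (S2 * g0 - S1 * g1) / det
        db1 = (S0 * g1 - S1 * g0) / det
        b0 += db0
        b1 = np.clip(b1 + db1, -20, 20)
        if max(np.abs(db0).max(), np.abs(db1).max()) < tol:
            break
    eta = np.clip(b0 + X * b1, -30, 30)
    w = expit(eta) * (1 - expit(eta))
    S0 = w.sum(axis=0)
    S1 = (w * X).sum(axis=0)
    S2 = (w * X * X).sum(axis=0)
    det = np.maximum(S0 * S2 - S1 * S1, 1e-12)
    se = np.sqrt(S0 / det)
    z = b1 / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"beta": b1, "se": se, "z": z, "p": p})


def _scan_to_sumstats(panel: GenotypePanel, fit: pd.DataFrame, n: int) -> pd.DataFrame:
    out = panel.variants.copy()
    out = out.rename(columns={"alt": "effect_allele", "ref": "other_allele"})
    for col in ["beta", "se", "z", "p"]:
        out[col] = fit[col].to_numpy()
    out["n"] = n
    out["maf"] = panel.maf()
    return out[["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                "beta", "se", "z", "p", "n", "maf"]]


def null_scan(panel: GenotypePanel, theta: float,
              rng: np.random.Generator) -> pd.DataFrame:
    """Summary statistics under the global null.

    The phenotype is Bernoulli(theta), independent of genotype; a
    degenerate draw (all cases or all controls) is redrawn and logged.
    """
    n = panel.n_individuals
    for _ in range(100):
        y = rng.binomial(1, theta, size=n)
        if 0 < y.sum() < n:
            break
        logger.info("null_scan: degenerate phenotype redrawn")
    fit = logistic_scan(panel.dosages, y)
    return _scan_to_sumstats(panel, fit, n)


def balanced_phenotype(panel: GenotypePanel, beta: np.ndarray, n: int,
                       rng: np.random.Generator,
                       max_factor: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Balanced case-control sample under logit P(Y=1) = sum_j beta_j X_ij.

    Dosages enter the log-odds centered (an implicit intercept
    -sum_j beta_j mean(X_j)), which pins the baseline prevalence near
    50% so a balanced sample is reachable for any causal configuration.
    Individuals are drawn (with replacement) from the panel,
    phenotypes sampled from the per-individual log-odds, and the pool
    oversampled until n/2 cases and n/2 controls are collected.
    Returns (row indices, phenotypes).
    """
    half = n // 2
    cases, controls = [], []
    factor = 4
    offset = float(np.nanmean(panel.dosages, axis=0) @ beta)
    while factor <= max_factor:
        idx = rng.integers(0, panel.n_individuals, size=factor * n)
        eta = panel.dosages[idx] @ beta - offset
        y = rng.random(len(idx)) < expit(eta)
        cases = idx[y][:half]
        controls = idx[~y][:half]
        if len(cases) == half and len(controls) == half:
            rows = np.concatenate([cases, controls])
            return rows, np.concatenate([np.ones(half), np.zeros(half)])
        factor *= 2
    raise ValueError("could not collect a balanced sample; effect sizes may "
                     "cause near-separation")


def _draw_effects(K: int, cfg: SimConfig, rng) -> np.ndarray:
    n_causal = max(1, int(round(cfg.causal_prop * K)))
    beta = np.zeros(K)
    idx = rng.choice(K, size=n_causal, replace=False)
    eff = np.full(n_causal, cfg.beta, dtype=float)
    if cfg.effect_signs == "mixed":
        eff *= rng.choice([-1.0, 1.0], size=n_causal)
    beta[idx] = eff
    return beta


def power_scan(panel: GenotypePanel, cfg: SimConfig, mode: str = "common",
               n_sample: int | None = None) -> SimResult:
    """Empirical power of the gene-level test under the alternative.

    Gene by gene and replicate by replicate: draw causal effects for
    ``causal_prop`` of the gene's SNPs, collect a balanced case-control
    sample of size ``n_sample`` (default: panel size), run the per-SNP
    logistic scan, and apply the gene-level test with the POET-shrunk
    panel LD. Power is the fraction of p-values below ``cfg.alpha``.
    """
    from .gene_assoc import common_chisq
    from .ld_panel import PoetConfig, compute_ld, poet_shrink
    rng = cfg.rng()
    n = n_sample or panel.n_individuals
    gene_models = panel.meta["gene_models"]
    cols = {g.gene_id: [i for i, v in enumerate(panel.variants["variant_id"])
                        if v.startswith(g.gene_id + "_")] for g in gene_models}
    pcfg = PoetConfig()
    p_out = np.ones((cfg.n_replicates, len(gene_models)))
    for gi, g in enumerate(gene_models):
        ci = cols[g.gene_id]
        ids = [panel.variants["variant_id"].iloc[i] for i in ci]
        R = poet_shrink(compute_ld(panel, ids), pcfg, n=panel.n_individuals)
        for rep in range(cfg.n_replicates):
            beta_g = np.zeros(panel.dosages.shape[1])
            beta_g[ci] = _draw_effects(len(ci), cfg, rng)
            rows, y = balanced_phenotype(panel, beta_g, n, rng)
            fit = logistic_scan(panel.dosages[np.ix_(rows, ci)], y)
            p_out[rep, gi] = common_chisq(fit["z"].to_numpy(), R).p
    return SimResult.from_pvalues(p_out, cfg.alpha)


def permute_expression(expr: CellTypeExpression, seed: int) -> CellTypeExpression:
    """Permute gene rows of E (and A jointly), breaking any link between
    gene-level statistics and expression while preserving the value
    multiset."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(expr.E))
    E = pd.DataFrame(expr.E.to_numpy()[perm], index=expr.E.index,
                     columns=expr.E.columns)
    A = pd.Series(expr.A.to_numpy()[perm], index=expr.A.index)
    return CellTypeExpression(E, A)


# ---------------------------------------------------------------------------
# end-to-end fixture

@dataclass
class FixtureBundle:
    """A complete miniature dataset plus its generating truth record."""
    panel: GenotypePanel
    sumstats: pd.DataFrame
    gene_models: list
    expression: CellTypeExpression
    truth: dict
    paths: dict = field(default_factory=dict)


def fixture_config(seed: int, **overrides) -> SimConfig:
    """Default end-to-end fixture design: 200 genes x 10 SNPs, a GWAS of
    2,000 balanced cases/controls scanned against a 500-individual
    panel, 8 cell types with one truly enriched."""
    base = dict(n_individuals=500, n_genes=200, n_snps_per_gene=10,
                latent_rho=0.6, causal_prop=0.4, beta=0.25,
                causal_gene_prop=0.2, n_cell_types=8, expr_shift=1.5,
                seed=seed)
    base.update(overrides)
    return SimConfig(**base)


def make_fixture(cfg: SimConfig, out_dir: str | None = None,
                 n_gwas: int = 2_000) -> FixtureBundle:
    """Generate a panel, an alternative-model GWAS, expression with one
    embedded trait-relevant cell type, and the truth record.

    Causal genes (a ``causal_gene_prop`` fraction) carry causal SNPs;
    the first cell type's expression is shifted up by ``expr_shift``
    log2 units exactly for causal genes, making it the ground-truth
    enriched cell type. The GWAS cohort of ``n_gwas`` balanced
    cases/controls is synthesized fresh from the same population model
    rather than resampled from the panel, so the panel plays its
    real-world role of an external LD reference and non-causal genes
    are exactly null. With ``out_dir`` the bundle is also written as
    PLINK bed/bim/fam, a summary-statistic TSV, BED gene models, an
    expression TSV, and a JSON truth record.
    """
    rng = cfg.rng()
    panel = synth_panel(SimConfig(**{**asdict(cfg),
                                     "seed": int(rng.integers(2 ** 31))}))
    gene_models = panel.meta["gene_models"]
    n_causal_genes = max(1, int(round(cfg.causal_gene_prop * cfg.n_genes)))
    causal_genes = sorted(rng.choice(cfg.n_genes, n_causal_genes, replace=False))
    causal_set = {gene_models[i].gene_id for i in causal_genes}

    beta = np.zeros(panel.dosages.shape[1])
    vids = panel.variants["variant_id"]
    for gi in causal_genes:
        gid = gene_models[gi].gene_id
        ci = np.flatnonzero(vids.str.startswith(gid + "_").to_numpy())
        beta[ci] = _draw_effects(len(ci), cfg, rng)

    # fresh cohort: oversample, then keep a balanced case/control subset
    half = n_gwas // 2
    offset = float(np.nanmean(panel.dosages, axis=0) @ beta)
    X_parts, y_parts, n_cases, n_controls = [], [], 0, 0
    while n_cases < half or n_controls < half:
        chunk = _synth_blocks(rng, 2 * n_gwas, panel.meta["gene_mafs"],
                              cfg.latent_rho)
        yc = rng.random(len(chunk)) < expit(chunk @ beta - offset)
        X_parts.append(chunk)
        y_parts.append(yc)
        n_cases += int(yc.sum())
        n_controls += int((~yc).sum())
    X_all, y_all = np.vstack(X_parts), np.concatenate(y_parts)
    keep = np.concatenate([np.flatnonzero(y_all)[:half],
                           np.flatnonzero(~y_all)[:half]])
    fit = logistic_scan(X_all[keep], y_all[keep].astype(float))
    sumstats = _scan_to_sumstats(panel, fit, n_gwas)

    gene_ids = [g.gene_id for g in gene_models]
    types = [f"celltype{t}" for t in range(cfg.n_cell_types)]
    E = np.maximum(rng.normal(4.0, 1.5, size=(cfg.n_genes, cfg.n_cell_types)), 0.0)
    is_causal = np.array([g in causal_set for g in gene_ids])
    E[is_causal, 0] += cfg.expr_shift
    expr = CellTypeExpression(pd.DataFrame(E, index=gene_ids, columns=types))

    truth = {"causal_genes": sorted(causal_set), "enriched_cell_type": types[0],
             "config": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(cfg).items()},
             "n_gwas": n_gwas}
    bundle = FixtureBundle(panel, sumstats, gene_models, expr, truth)
    if out_dir:
        bundle.paths = _write_fixture(bundle, out_dir)
    return bundle


def _write_fixture(b: FixtureBundle, out_dir: str) -> dict:
    from . import plink
    os.makedirs(out_dir, exist_ok=True)
    prefix = os.path.join(out_dir, "panel")
    bim = pd.DataFrame({
        "chrom": b.panel.variants["chrom"],
        "variant_id": b.panel.variants["variant_id"], "cm": 0,
        "pos": b.panel.variants["pos"],
        "a1": b.panel.variants["alt"], "a2": b.panel.variants["ref"],
    })
    plink.write_bed(prefix, b.panel.dosages, bim)
    paths = {"panel": prefix}
    paths["sumstats"] = os.path.join(out_dir, "sumstats.tsv")
    out = b.sumstats.rename(columns={
        "variant_id": "SNP", "chrom": "CHR", "pos": "BP",
        "effect_allele": "A1", "other_allele": "A2", "beta": "BETA",
        "se": "SE", "z": "Z", "p": "P", "n": "N", "maf": "MAF"})
    out.to_csv(paths["sumstats"], sep="\t", index=False)
    paths["genes"] = os.path.join(out_dir, "genes.bed")
    with open(paths["genes"], "w") as fh:
        for g in b.gene_models:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    paths["expression"] = os.path.join(out_dir, "expression.tsv")
    b.expression.E.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    paths["truth"] = os.path.join(out_dir, "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(b.truth, fh, indent=1)
    return paths
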