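"""Gene-level association statistics from SNP-level z-scores.

Three tests are provided, all quadratic forms in the SNP z-scores with
a reference-panel LD matrix standing in for the covariance of the
z-scores under the null:

* common variants: Q_c = z' R^{-1} z ~ chi-square with K df;
* rare variants: a burden statistic reconstructed from score-scale
  summary statistics, Q_r = (w'z)^2 / (w'Rw) ~ chi-square with 1 df,
  with inverse-standard-error weights w_j = 1/se_j;
* joint: the rare variants collapse to one pseudo-SNP whose z-score is
  the burden z, appended to the common z vector, Q = z*' R*^{-1} z* ~
  chi-square with K+1 df.

P-values are carried on the log scale so that extreme signals
(p < 1e-300) survive; ``p`` is the exponentiated value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .ld_panel import (GenotypePanel, LdMatrix, NotPositiveDefiniteError,
                       PoetConfig, _pairwise_corr, compute_ld, poet_shrink,
                       pseudo_snp_column)

logger = logging.getLogger(__name__)


@dataclass
class GeneStat:
    """One gene-level quadratic-form test result."""
    gene_id: str
    test_type: str  # {common, rare, joint}
    Q: float
    df: int
    p: float
    log_p: float
    K_common: int = 0
    M_rare: int = 0
    z_r: float | None = None
    mac_rare: float = 0.0
    chrom: str = ""
    start: int = 0
    end: int = 0


def _chol_quadform(z: np.ndarray, R: np.ndarray) -> float:
    """z' R^{-1} z via a Cholesky solve (no explicit inverse)."""
    try:
        c, low = linalg.cho_factor(R, lower=True)
    except np.linalg.LinAlgError as e:
        raise NotPositiveDefiniteError(
            "LD matrix is not positive definite; regularize it with "
            "poet_shrink before testing") from e
    y = linalg.solve_triangular(c, z, lower=low)
    return float(y @ y)


def _chi2_stat(gene_id: str, test_type: str, Q: float, df: int, **kw) -> GeneStat:
    log_p = float(stats.chi2.logsf(Q, df))
    return GeneStat(gene_id, test_type, float(Q), int(df),
                    p=float(np.exp(log_p)), log_p=log_p, **kw)


def common_chisq(z, R: LdMatrix | np.ndarray, gene_id: str = "") -> GeneStat:
    """Common-variant chi-square test Q_c = z' R^{-1} z on K df."""
    Rm = R.R if isinstance(R, LdMatrix) else np.asarray(R, dtype=float)
    z = np.asarray(z, dtype=float)
    if Rm.shape[0] != z.shape[0]:
        raise ValueError("z and R dimension mismatch")
    Q = _chol_quadform(z, Rm)
    return _chi2_stat(gene_id, "common", Q, len(z), K_common=len(z))


def burden(z, w, R: LdMatrix | np.ndarray, gene_id: str = "") -> tuple[float, GeneStat]:
    """Rare-variant burden test from z-scores.

    Returns the pseudo-SNP z-score z_r = w'z / sqrt(w'Rw) and the
    burden statistic Q_r = z_r^2 on 1 df.
    """
    Rm = R.R if isinstance(R, LdMatrix) else np.asarray(R, dtype=float)
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(z) == len(w) == Rm.shape[0]):
        raise ValueError("z, w, R dimension mismatch")
    if np.any(w <= 0):
        raise ValueError("burden weights must be positive")
    denom = float(w @ Rm @ w)
    if denom <= 0:
        raise ValueError("w'Rw <= 0: the rare-variant LD matrix is broken; "
                         "regularize it first")
    z_r = float(w @ z) / np.sqrt(denom)
    gs = _chi2_stat(gene_id, "rare", z_r ** 2, 1, M_rare=len(z), z_r=z_r)
    return z_r, gs


def joint_chisq(z_common, z_r: float, R_star: LdMatrix | np.ndarray,
                gene_id: str = "", M_rare: int = 0) -> GeneStat:
    """Joint common + pseudo-SNP test Q = z*' R*^{-1} z* on K+1 df."""
    Rm = R_star.R if isinstance(R_star, LdMatrix) else np.asarray(R_star, dtype=float)
    z_common = np.asarray(z_common, dtype=float)
    K = len(z_common)
    if Rm.shape[0] != K + 1:
        raise ValueError("R_star must have dimension K+1")
    z_star = np.append(z_common, z_r)
    Q = _chol_quadform(z_star, Rm)
    return _chi2_stat(gene_id, "joint", Q, K + 1, K_common=K, M_rare=M_rare,
                      z_r=float(z_r))


def rare_weights(rare_snps: pd.DataFrame) -> np.ndarray:
    """Inverse-standard-error burden weights w_j = 1/se_j."""
    se = rare_snps["se"].to_numpy(dtype=float)
    if np.any(~(se > 0)):
        raise ValueError("rare-variant standard errors must be positive")
    return 1.0 / se


def build_joint_ld(panel: GenotypePanel, gene, cfg: PoetConfig | None = None,
                   method: str = "analytic") -> tuple[LdMatrix, np.ndarray]:
    """Shrunk (K+1) LD matrix over a gene's common SNPs plus pseudo-SNP.

    ``analytic`` (default) POET-shrinks the full common+rare LD block
    and collapses the rare part: cross entries are
    (sum_l w_l R_jl) / sqrt(w'R_rr w), exactly the correlation of SNP j
    with the w-weighted standardized rare-dosage sum, so the result is
    positive definite whenever the full block is. ``pseudo-column``
    instead synthesizes the collapsed dosage column and shrinks the
    (K+1)-dimensional sample correlation directly.

    Returns the joint matrix and the rare-block LD (for the burden
    denominator, kept consistent with the joint cross terms).
    """
    common_ids = list(gene.common_snps["variant_id"])
    rare_ids = list(gene.rare_snps["variant_id"])
    K, M = len(common_ids), len(rare_ids)
    w = rare_weights(gene.rare_snps)
    if method == "pseudo-column":
        X = np.hstack([panel.columns(common_ids),
                       pseudo_snp_column(panel, gene.rare_snps)[:, None]])
        R = _pairwise_corr(X)
        np.fill_diagonal(R, 1.0)
        sample = LdMatrix(R, common_ids + ["pseudo"], n=panel.n_individuals)
        shrunk = poet_shrink(sample, cfg, n=panel.n_individuals)
        R_rr = compute_ld(panel, rare_ids)
        return shrunk, poet_shrink(R_rr, cfg, n=panel.n_individuals).R
    full = compute_ld(panel, common_ids + rare_ids)
    full = poet_shrink(full, cfg, n=panel.n_individuals)
    R_cc = full.R[:K, :K]
    R_cr = full.R[:K, K:]
    R_rr = full.R[K:, K:]
    s = np.sqrt(float(w @ R_rr @ w))
    cross = R_cr @ w / s
    R_star = np.empty((K + 1, K + 1))
    R_star[:K, :K] = R_cc
    R_star[:K, K] = cross
    R_star[K, :K] = cross
    R_star[K, K] = 1.0
    out = LdMatrix(R_star, common_ids + ["pseudo"], shrunk=True,
                   min_eigenvalue=float(np.linalg.eigvalsh(R_star)[0]),
                   n=panel.n_individuals, meta=dict(full.meta))
    return out, R_rr


def _test_one_gene(gene, panel, mode, cfg):
    g = gene.gene
    loc = dict(chrom=g.chrom, start=g.start, end=g.end, mac_rare=gene.mac_rare)
    has_rare = gene.n_rare > 0 and not gene.rare_skipped
    try:
        if mode == "rare":
            if not has_rare:
                return None
            R = poet_shrink(compute_ld(panel, list(gene.rare_snps["variant_id"])),
                            cfg, n=panel.n_individuals)
            _, gs = burden(gene.rare_snps["z"].to_numpy(), rare_weights(gene.rare_snps),
                           R, gene_id=g.gene_id)
        elif mode == "common" or (mode == "joint" and not has_rare):
            if gene.n_common == 0:
                return None
            R = poet_shrink(compute_ld(panel, list(gene.common_snps["variant_id"])),
                            cfg, n=panel.n_individuals)
            gs = common_chisq(gene.common_snps["z"].to_numpy(), R, gene_id=g.gene_id)
            gs.M_rare = 0
        elif mode == "joint":
            if gene.n_common == 0:
                R = poet_shrink(compute_ld(panel, list(gene.rare_snps["variant_id"])),
                                cfg, n=panel.n_individuals)
                _, gs = burden(gene.rare_snps["z"].to_numpy(),
                               rare_weights(gene.rare_snps), R, gene_id=g.gene_id)
            else:
                R_star, R_rr = build_joint_ld(panel, gene, cfg)
                z_r, _ = burden(gene.rare_snps["z"].to_numpy(),
                                rare_weights(gene.rare_snps), R_rr)
                gs = joint_chisq(gene.common_snps["z"].to_numpy(), z_r, R_star,
                                 gene_id=g.gene_id, M_rare=gene.n_rare)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    except NotPositiveDefiniteError:
        logger.warning("gene %s: singular LD after shrinkage; reporting p=NA",
                       g.gene_id)
        gs = GeneStat(g.gene_id, mode, np.nan, max(gene.n_common, 1),
                      p=np.nan, log_p=np.nan, K_common=gene.n_common,
                      M_rare=gene.n_rare)
    for k, v in loc.items():
        setattr(gs, k, v)
    return gs


def gene_scan(genes, panel: GenotypePanel, mode: str = "common",
              cfg: PoetConfig | None = None, n_jobs: int = 1) -> list[GeneStat]:
    """Run the chosen gene-level test over annotated genes.

    Genes are processed in genomic order, chunked per chromosome when
    parallelized; results do not depend on the chunking. Genes with no
    eligible SNPs for the mode are skipped with a log message.
    """
    ordered = sorted(genes, key=lambda a: (a.gene.chrom, a.gene.start, a.gene.gene_id))
    if n_jobs != 1:
        from joblib import Parallel, delayed
        chroms: dict[str, list] = {}
        for g in ordered:
            chroms.setdefault(g.gene.chrom, []).append(g)
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(lambda gs: [_test_one_gene(g, panel, mode, cfg) for g in gs])(gs)
            for gs in chroms.values())
        results = [r for chunk in chunks for r in chunk]
    else:
        results = [_test_one_gene(g, panel, mode, cfg) for g in ordered]
    skipped = sum(r is None for r in results)
    if skipped:
        logger.info("gene_scan: skipped %d ineligible genes", skipped)
    return [r for r in results if r is not None]


def gene_stats_table(stats: list[GeneStat]) -> pd.DataFrame:
    """Tabulate GeneStat results (gene-test CLI output format)."""
    return pd.DataFrame([{
        "gene_id": s.gene_id, "chrom": s.chrom, "start": s.start, "end": s.end,
        "K": s.K_common, "M": s.M_rare, "MAC": s.mac_rare,
        "test_type": s.test_type, "Q": s.Q, "df": s.df, "p": s.p,
    } for s in stats])
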