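"""Correlation between gene-level chi-square statistics.

Nearby genes share cis-SNPs and LD, so their quadratic-form statistics
Q_s and Q_t are correlated. Under joint normality of the SNP z-scores,

    cor(Q_s, Q_t) = ||R_s^{-1/2} R_st R_t^{-1/2}||_F^2 / sqrt(K_s K_t),

the squared Frobenius norm of the whitened cross-correlation block.
The same quantity is the sum of squared entries of the off-diagonal
Cholesky block of the jointly whitened correlation matrix; that route
is kept as a cross-check (see tests). Correlations are computed only
for pairs within a sliding window of d genes and a distance cap, which
gives the sparse banded gene-gene matrix P used by the enrichment GLS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .ld_panel import (GenePairBlock, GenotypePanel, PoetConfig,
                       block_ld_for_genes, gene_distance)

logger = logging.getLogger(__name__)


@dataclass
class GenePairCorr:
    gene_s: str
    gene_t: str
    rho: float
    K_s: int
    K_t: int


@dataclass
class GeneCorrMatrix:
    """Sparse banded gene-gene correlation matrix P (unit diagonal)."""
    P: sparse.csr_matrix
    gene_ids: list
    d: int
    max_dist: int
    delta: float = 0.0  # diagonal-shrinkage PD repair weight
    meta: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.P.shape[0]

    def to_triplets(self) -> pd.DataFrame:
        coo = sparse.triu(self.P, k=1).tocoo()
        return pd.DataFrame({
            "gene_s": [self.gene_ids[i] for i in coo.row],
            "gene_t": [self.gene_ids[j] for j in coo.col],
            "rho": coo.data,
        })


def _inv_sqrt(M: np.ndarray) -> np.ndarray:
    lam, vec = np.linalg.eigh(M)
    if lam[0] <= 0:
        raise np.linalg.LinAlgError(
            "gene LD partition is not positive definite; apply POET shrinkage")
    return (vec / np.sqrt(lam)) @ vec.T


def rho_pair(block: GenePairBlock) -> GenePairCorr:
    """Correlation of the two genes' chi-square statistics.

    Whitens the cross-LD block by the two within-gene matrices and
    takes its squared Frobenius norm over sqrt(K_s K_t). The value is
    clipped to [0, 1] with a warning if it lands outside numerically.
    """
    K_s, K_t = len(block.idx_s), len(block.idx_t)
    C = _inv_sqrt(block.R_s) @ block.R_st @ _inv_sqrt(block.R_t)
    rho = float(np.sum(C * C)) / np.sqrt(K_s * K_t)
    if rho > 1.0 + 1e-9:
        warnings.warn(f"rho={rho:.6f} outside [0,1]; clipping", stacklevel=2)
    rho = float(np.clip(rho, 0.0, 1.0))
    return GenePairCorr(block.gene_s, block.gene_t, rho, K_s, K_t)


def rho_pair_cholesky(block: GenePairBlock) -> float:
    """Cholesky-route equivalent of :func:`rho_pair` (cross-check only).

    Builds the jointly whitened matrix [[I, C], [C', I]], factors it,
    and sums the squared entries of the off-diagonal block of L.
    """
    K_s, K_t = len(block.idx_s), len(block.idx_t)
    C = _inv_sqrt(block.R_s) @ block.R_st @ _inv_sqrt(block.R_t)
    Rt = np.block([[np.eye(K_s), C], [C.T, np.eye(K_t)]])
    L = np.linalg.cholesky(Rt + 1e-12 * np.eye(K_s + K_t))
    return float(np.sum(L[K_s:, :K_s] ** 2)) / np.sqrt(K_s * K_t)


def build_gene_corr(genes, panel: GenotypePanel, d: int = 10,
                    max_dist: int = 5_000_000, cfg: PoetConfig | None = None,
                    include_pseudo: bool = False,
                    eig_floor: float = 1e-8) -> GeneCorrMatrix:
    """Assemble the sparse gene-gene correlation matrix P.

    ``genes`` are AnnotatedGene objects (pruned, classified), ordered
    here by genomic position per chromosome. Each within-chromosome
    pair with index separation <= d-1 and body-to-body distance <=
    ``max_dist`` is evaluated directly from its two-gene joint LD
    block; all other entries are exactly zero. If the assembled matrix
    has minimum eigenvalue <= ``eig_floor`` it is repaired by diagonal
    shrinkage P <- (1-delta) P + delta I with the smallest delta in
    {0.01, 0.02, ...} that restores positive definiteness.
    """
    if d < 2:
        raise ValueError("window size d must be >= 2")
    ordered = sorted(genes, key=lambda a: (a.gene.chrom, a.gene.start, a.gene.gene_id))
    ids = [g.gene.gene_id for g in ordered]
    N = len(ordered)
    rows, cols, vals = [], [], []
    # positions of each chromosome's genes in the global order
    chrom_idx: dict[str, list[int]] = {}
    for i, g in enumerate(ordered):
        chrom_idx.setdefault(g.gene.chrom, []).append(i)
    for idxs in chrom_idx.values():
        for a, i in enumerate(idxs):
            for j in idxs[a + 1:a + d]:
                if gene_distance(ordered[i].gene, ordered[j].gene) > max_dist:
                    continue
                block = block_ld_for_genes(panel, ordered, (i, j), d=d,
                                           max_dist=max_dist, cfg=cfg,
                                           include_pseudo=include_pseudo)
                pc = rho_pair(block)
                if pc.rho != 0.0:
                    rows += [i, j]
                    cols += [j, i]
                    vals += [pc.rho, pc.rho]
    P = sparse.csr_matrix((vals, (rows, cols)), shape=(N, N))
    P = P + sparse.identity(N, format="csr")
    delta = 0.0
    dense = P.toarray()
    min_eig = float(np.linalg.eigvalsh(dense)[0])
    if min_eig <= eig_floor:
        for delta in np.arange(0.01, 1.0, 0.01):
            repaired = (1 - delta) * dense + delta * np.eye(N)
            min_eig = float(np.linalg.eigvalsh(repaired)[0])
            if min_eig > eig_floor:
                P = sparse.csr_matrix(repaired)
                logger.info("build_gene_corr: PD repair with delta=%.2f", delta)
                break
        else:
            raise np.linalg.LinAlgError("PD repair failed")
        delta = float(delta)
    return GeneCorrMatrix(P, ids, d=d, max_dist=max_dist, delta=delta,
                          meta={"min_eigenvalue": min_eig})


def write_gene_corr(gc: GeneCorrMatrix, path: str) -> None:
    """Persist P as a triplet TSV with a '#' metadata header line."""
    with open(path, "w") as fh:
        fh.write(f"# d={gc.d} max_dist={gc.max_dist} delta={gc.delta}\n")
        gc.to_triplets().to_csv(fh, sep="\t", index=False)


def read_gene_corr(path: str, gene_ids: list) -> GeneCorrMatrix:
    """Load a triplet TSV back into a GeneCorrMatrix over ``gene_ids``."""
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(kv.split("=") for kv in first[1:].split())
            trip = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            trip = pd.read_csv(fh, sep="\t")
    index = {g: i for i, g in enumerate(gene_ids)}
    N = len(gene_ids)
    rows, cols, vals = [], [], []
    for r in trip.itertuples(index=False):
        if r.gene_s in index and r.gene_t in index:
            i, j = index[r.gene_s], index[r.gene_t]
            rows += [i, j]
            cols += [j, i]
            vals += [r.rho, r.rho]
    P = sparse.csr_matrix((vals, (rows, cols)), shape=(N, N)) + sparse.identity(N, format="csr")
    return GeneCorrMatrix(P, list(gene_ids), d=int(meta.get("d", 10)),
                          max_dist=int(float(meta.get("max_dist", 5_000_000))),
                          delta=float(meta.get("delta", 0.0)))
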