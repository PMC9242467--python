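"""Cell-type- and tissue-level expression covariates.

The enrichment regression takes one expression column per cell type,
on a log2(RPKM + 1) (single cell, pooled per cell type) or
log2(TPM + 1) (bulk tissue) scale, together with the per-gene average
across cell types as a baseline covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

logger = logging.getLogger(__name__)


@dataclass
class CellTypeExpression:
    """Genes x cell-types log2 expression with per-gene average.

    ``E`` is a DataFrame (genes x cell types); ``A`` is its row mean.
    """
    E: pd.DataFrame
    A: pd.Series = None

    def __post_init__(self):
        if not self.E.index.is_unique:
            raise ValueError("gene ids must be unique")
        if self.A is None:
            self.A = self.E.mean(axis=1)

    @property
    def gene_ids(self):
        return list(self.E.index)

    @property
    def cell_types(self):
        return list(self.E.columns)


@dataclass
class CellCounts:
    """Cell-level counts with per-cell type labels and gene lengths."""
    counts: np.ndarray | sparse.spmatrix  # cells x genes
    cell_types: np.ndarray  # label per cell
    gene_ids: list
    gene_lengths: np.ndarray | None = None  # bp, for RPKM
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cell_types = np.asarray(self.cell_types)
        if self.counts.shape[0] != len(self.cell_types):
            raise ValueError("cell-type labels must cover all cells")
        if self.counts.shape[1] != len(self.gene_ids):
            raise ValueError("gene ids must match count columns")
        if self.gene_lengths is not None:
            self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
            if np.any(self.gene_lengths <= 0):
                raise ValueError("gene lengths must be positive")

    def dense(self) -> np.ndarray:
        c = self.counts
        return np.asarray(c.todense()) if sparse.issparse(c) else np.asarray(c, dtype=float)


def pool_cell_type_expression(cc: CellCounts) -> CellTypeExpression:
    """Pool counts per cell type and convert to log2(RPKM + 1).

    RPKM uses the pooled library size of the cell type (total counts
    over its cells) and the gene length in bp; without gene lengths a
    counts-per-million (CPM-style) pooling is used instead. The
    pseudo-count inside the log2 is 1.
    """
    X = cc.dense()
    types = pd.unique(cc.cell_types)
    cols = {}
    for t in types:
        pooled = X[cc.cell_types == t].sum(axis=0)
        lib = pooled.sum()
        if lib <= 0:
            raise ValueError(f"cell type {t!r} has zero total counts")
        if cc.gene_lengths is not None:
            expr = pooled * 1e9 / (lib * cc.gene_lengths)
        else:
            expr = pooled * 1e6 / lib
        cols[t] = np.log2(expr + 1.0)
    E = pd.DataFrame(cols, index=cc.gene_ids)
    return CellTypeExpression(E)


def select_hvg(cc: CellCounts, n_top: int = 8_000) -> list:
    """Top highly variable genes by normalized dispersion.

    Ranks genes by their dispersion standardized within mean-expression
    bins (the Seurat-style recipe, via scanpy) on log-normalized counts
    and keeps the ``n_top`` highest; if fewer genes exist, all are kept.
    """
    if len(cc.gene_ids) <= n_top:
        return list(cc.gene_ids)
    import anndata as ad
    import scanpy as sc
    adata = ad.AnnData(X=sparse.csr_matrix(cc.dense()))
    adata.var_names = [str(g) for g in cc.gene_ids]
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_top)
    disp = adata.var["dispersions_norm"].to_numpy()
    order = np.argsort(-np.nan_to_num(disp, nan=-np.inf), kind="stable")[:n_top]
    keep = sorted(order)
    return [cc.gene_ids[i] for i in keep]


def tissue_specificity_filter(E_bulk: pd.DataFrame, threshold: float = 5.0) -> list:
    """Genes highly specific to at least one tissue.

    The specificity score of gene g in tissue t is the z-score of its
    expression across tissues, (E_gt - mean_t) / sd_t with the
    population (ddof=0) standard deviation; genes whose maximum score
    exceeds ``threshold`` are kept. Genes constant across tissues
    (sd = 0) score 0 everywhere and are dropped.
    """
    X = E_bulk.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(sd > 0, (X - mean) / sd, 0.0)
    keep = score.max(axis=1) > threshold
    logger.info("tissue_specificity_filter: kept %d of %d genes",
                int(keep.sum()), len(E_bulk))
    return list(E_bulk.index[keep])


def marker_test(cc: CellCounts, target: str, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene one-sided rank-sum test of target cells vs the rest.

    Tests whether each gene is expressed higher in the target cell
    type (Wilcoxon rank-sum, alternative 'greater'), with Bonferroni-
    adjusted significance calls. Genes with no variation anywhere get
    p = 1 by convention.
    """
    if target not in set(cc.cell_types):
        raise ValueError(f"cell type {target!r} not present")
    if len(pd.unique(cc.cell_types)) < 2:
        raise ValueError("marker_test needs at least two cell types")
    X = cc.dense()
    in_t = cc.cell_types == target
    a, b = X[in_t], X[~in_t]
    res = stats.mannwhitneyu(a, b, alternative="greater", axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    flat = X.std(axis=0) == 0
    p[flat] = 1.0
    G = X.shape[1]
    out = pd.DataFrame({"p": p, "p_bonferroni": np.minimum(p * G, 1.0)},
                       index=cc.gene_ids)
    out["significant"] = out["p"] < alpha / G
    return out


def read_cell_counts(mtx_path: str, genes_path: str, cells_path: str,
                     labels_path: str, lengths_path: str | None = None) -> CellCounts:
    """Load MatrixMarket counts (cells x genes or genes x cells) with
    gene/cell id TSVs and a per-cell label TSV."""
    from scipy.io import mmread
    M = mmread(mtx_path).tocsr()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].tolist()
    if M.shape == (len(genes), len(cells)) and len(genes) != len(cells):
        M = M.T.tocsr()
    labels_df = pd.read_csv(labels_path, sep="\t", header=None, index_col=0)
    labels = labels_df.loc[cells, 1].to_numpy()
    lengths = None
    if lengths_path:
        lg = pd.read_csv(lengths_path, sep="\t", header=None, index_col=0)
        lengths = lg.loc[genes, 1].to_numpy(dtype=float)
    return CellCounts(M, labels, genes, lengths)


def read_bulk_expression(path: str, log_transform: bool = True) -> CellTypeExpression:
    """Genes x tissues TPM table; optionally log2(TPM + 1)-transformed."""
    E = pd.read_csv(path, sep="\t", index_col=0)
    if log_transform:
        E = np.log2(E + 1.0)
    return CellTypeExpression(E)
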