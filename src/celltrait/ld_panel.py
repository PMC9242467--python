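"""Reference-panel LD matrices and POET shrinkage.

Gene-level quadratic-form tests need a well-conditioned SNP correlation
matrix. Sample LD matrices from a few hundred reference individuals are
ill-conditioned (often rank-deficient) when the SNP count approaches
the sample size, so they are regularized with the POET estimator:
the top spiked eigencomponents are retained and the residual
off-diagonals are adaptively soft-thresholded, with the threshold
chosen as the smallest grid value that makes the result positive
definite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    pass


@dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix with aligned variant metadata.

    Dosages count copies of the alt (counting) allele; missing entries
    are NaN.
    """
    dosages: np.ndarray
    variants: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage columns must match variant metadata rows")
        self._index = {v: i for i, v in enumerate(self.variants["variant_id"])}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def columns(self, snp_ids) -> np.ndarray:
        try:
            idx = [self._index[s] for s in snp_ids]
        except KeyError as e:
            raise KeyError(f"variant {e.args[0]!r} not in panel") from None
        return self.dosages[:, idx]

    def maf(self, snp_ids=None) -> np.ndarray:
        x = self.dosages if snp_ids is None else self.columns(snp_ids)
        freq = np.nanmean(x, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class LdMatrix:
    """A (possibly POET-shrunk) SNP Pearson-correlation matrix."""
    R: np.ndarray
    snp_ids: list
    shrunk: bool = False
    min_eigenvalue: float = np.nan
    n: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.R.shape[0]


@dataclass
class PoetConfig:
    """POET tuning: spike count H, threshold grid and rate, PD floor.

    The entrywise threshold is ``c * rate`` with ``rate`` defaulting to
    sqrt(log K / n); ``c`` is the smallest grid value whose shrunk
    matrix has minimum eigenvalue above ``eps_pd``. H="auto" picks the
    spike count by the eigenvalue-ratio rule (argmax of consecutive
    eigenvalue ratios over the leading half, capped at ``h_cap``).
    """
    H: int | str = "auto"
    threshold_grid: tuple = tuple(np.round(np.arange(0.1, 2.01, 0.1), 2))
    rate: float | None = None
    eps_pd: float = 1e-4
    h_cap: int = 10

    def __post_init__(self):
        if len(self.threshold_grid) == 0:
            raise ValueError("threshold_grid must be non-empty")
        if self.H != "auto" and int(self.H) < 0:
            raise ValueError("H must be >= 0 or 'auto'")


def _pairwise_corr(x: np.ndarray) -> np.ndarray:
    """Pearson correlation over pairwise-complete rows."""
    if np.isnan(x).any():
        return pd.DataFrame(x).corr(min_periods=2).to_numpy()
    with np.errstate(invalid="ignore"):
        return np.atleast_2d(np.corrcoef(x, rowvar=False))


def compute_ld(panel: GenotypePanel, snp_ids) -> LdMatrix:
    """Sample LD matrix for the requested SNPs.

    Monomorphic or all-missing SNPs have undefined correlations and are
    dropped with a warning; fewer than two complete observation pairs
    is an error.
    """
    if panel.n_individuals < 2:
        raise ValueError("need at least 2 individuals to estimate LD")
    snp_ids = list(snp_ids)
    x = panel.columns(snp_ids)
    sd = np.nanstd(x, axis=0)
    ok = (sd > 0) & (np.sum(~np.isnan(x), axis=0) >= 2)
    if not ok.all():
        dropped = [s for s, o in zip(snp_ids, ok) if not o]
        logger.warning("compute_ld: dropping %d undefined SNPs: %s",
                       len(dropped), dropped[:5])
        snp_ids = [s for s, o in zip(snp_ids, ok) if o]
        x = x[:, ok]
    if x.shape[1] == 0:
        raise ValueError("no SNPs with defined correlations")
    R = _pairwise_corr(x)
    if np.isnan(R).any():
        raise ValueError("fewer than 2 complete pairs for some SNP pair")
    np.fill_diagonal(R, 1.0)
    eig = np.linalg.eigvalsh(R)
    return LdMatrix(R, snp_ids, shrunk=False, min_eigenvalue=float(eig[0]),
                    n=panel.n_individuals)


class PanelLdProvider:
    """Adapter exposing ``corr(ids)`` for LD pruning against a panel."""

    def __init__(self, panel: GenotypePanel):
        self.panel = panel

    def corr(self, snp_ids) -> np.ndarray:
        x = self.panel.columns(snp_ids)
        R = _pairwise_corr(x)
        return np.nan_to_num(R, nan=0.0)


def _auto_H(eigvals_desc: np.ndarray, cap: int) -> int:
    K = len(eigvals_desc)
    if K < 2:
        return 0
    jmax = max(1, min(K // 2, K - 1))
    lam = np.maximum(eigvals_desc, 1e-12)
    ratios = lam[:jmax] / lam[1:jmax + 1]
    return int(min(np.argmax(ratios) + 1, cap, K))


def poet_shrink(R_sample: LdMatrix, cfg: PoetConfig | None = None,
                n: int | None = None) -> LdMatrix:
    """POET shrinkage of a sample correlation matrix.

    Eigendecomposes R, keeps the top-H spiked components, soft-
    thresholds the residual off-diagonals entrywise at ``c * rate``
    (diagonal untouched), and returns the sum for the smallest grid
    constant c that yields minimum eigenvalue > ``eps_pd``.
    """
    cfg = cfg or PoetConfig()
    n = n if n is not None else R_sample.n
    if n is None:
        raise ValueError("sample count n required for the threshold rate")
    R = np.asarray(R_sample.R, dtype=float)
    K = R.shape[0]
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("input correlation matrix must be symmetric")
    R = (R + R.T) / 2.0
    lam, vec = np.linalg.eigh(R)
    lam, vec = lam[::-1], vec[:, ::-1]
    H = _auto_H(lam, cfg.h_cap) if cfg.H == "auto" else min(int(cfg.H), K)
    spike = (vec[:, :H] * lam[:H]) @ vec[:, :H].T if H > 0 else np.zeros_like(R)
    resid = R - spike
    rate = cfg.rate if cfg.rate is not None else np.sqrt(np.log(max(K, 2)) / n)
    diag = np.diag(np.diag(resid))
    off = resid - diag
    for c in cfg.threshold_grid:
        tau = c * rate
        off_t = np.sign(off) * np.maximum(np.abs(off) - tau, 0.0)
        np.fill_diagonal(off_t, 0.0)
        out = spike + diag + off_t
        out = (out + out.T) / 2.0
        min_eig = float(np.linalg.eigvalsh(out)[0])
        if min_eig > cfg.eps_pd:
            meta = dict(R_sample.meta)
            meta.update({"poet_H": H, "poet_c": float(c), "poet_tau": float(tau),
                         "poet_rule": "soft-threshold"})
            return LdMatrix(out, list(R_sample.snp_ids), shrunk=True,
                            min_eigenvalue=min_eig, n=n, meta=meta)
    raise NotPositiveDefiniteError(
        "no grid constant achieved positive definiteness; extend threshold_grid")


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.where(np.isnan(x), np.nanmean(x, axis=0), x)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def pseudo_snp_column(panel: GenotypePanel, rare_snps: pd.DataFrame) -> np.ndarray:
    """Collapsed rare-variant column: the 1/se-weighted sum of
    standardized rare dosages. Its panel correlations with other SNPs
    reproduce the analytic pseudo-SNP cross-correlations."""
    x = _standardize(panel.columns(list(rare_snps["variant_id"])))
    w = 1.0 / rare_snps["se"].to_numpy(dtype=float)
    return x @ w


@dataclass
class GenePairBlock:
    """Joint shrunk LD over two genes' SNPs with recoverable partitions.

    ``idx_s``/``idx_t`` index each gene's SNPs (pseudo-SNP last when
    present) inside the joint matrix; genes sharing SNPs index the same
    joint rows in both partitions.
    """
    gene_s: str
    gene_t: str
    ld: LdMatrix
    idx_s: np.ndarray
    idx_t: np.ndarray

    @property
    def R_s(self) -> np.ndarray:
        return self.ld.R[np.ix_(self.idx_s, self.idx_s)]

    @property
    def R_t(self) -> np.ndarray:
        return self.ld.R[np.ix_(self.idx_t, self.idx_t)]

    @property
    def R_st(self) -> np.ndarray:
        return self.ld.R[np.ix_(self.idx_s, self.idx_t)]


def gene_distance(g1, g2) -> int:
    """Gap in bp between two gene bodies (0 if they overlap)."""
    return max(0, max(g1.start, g2.start) - min(g1.end, g2.end))


def block_ld_for_genes(panel: GenotypePanel, genes, pair: tuple[int, int],
                       d: int = 10, max_dist: int = 5_000_000,
                       cfg: PoetConfig | None = None,
                       include_pseudo: bool = False) -> GenePairBlock:
    """POET-shrunk joint LD block for a pair of (position-ordered) genes.

    ``pair`` holds indices into ``genes`` (AnnotatedGene, pruned and
    classified). The pair must sit within the sliding window (index
    separation <= d-1), within ``max_dist``, and on one chromosome;
    cross-chromosome correlations are fixed at zero by contract and the
    operation is refused. With ``include_pseudo`` a collapsed rare-
    variant pseudo-SNP column is appended for each gene that passed the
    MAC filter.
    """
    si, ti = pair
    gs, gt = genes[si], genes[ti]
    if gs.gene.chrom != gt.gene.chrom:
        raise ValueError("cross-chromosome gene pairs have zero correlation "
                         "by contract; no block is computed")
    if abs(si - ti) > d - 1:
        raise ValueError(f"pair {si},{ti} outside sliding window d={d}")
    if gene_distance(gs.gene, gt.gene) > max_dist:
        raise ValueError("gene pair beyond max_dist")

    def gene_cols(g):
        ids = list(g.common_snps["variant_id"])
        cols = [panel.columns(ids)] if ids else []
        labels = list(ids)
        if include_pseudo and len(g.rare_snps) and not g.rare_skipped:
            cols.append(pseudo_snp_column(panel, g.rare_snps)[:, None])
            labels.append(f"{g.gene.gene_id}::pseudo")
        if not labels:
            raise ValueError(f"gene {g.gene.gene_id} has no eligible SNPs")
        return np.hstack(cols), labels

    xs, ls = gene_cols(gs)
    xt, lt = gene_cols(gt)
    labels, idx_s, idx_t, col_list = [], [], [], []
    seen = {}
    for x, lab, idx in ((xs, ls, idx_s), (xt, lt, idx_t)):
        for j, name in enumerate(lab):
            if name not in seen:
                seen[name] = len(labels)
                labels.append(name)
                col_list.append(x[:, j])
            idx.append(seen[name])
    X = np.column_stack(col_list)
    R = _pairwise_corr(X)
    np.fill_diagonal(R, 1.0)
    sample = LdMatrix(R, labels, n=panel.n_individuals)
    shrunk = poet_shrink(sample, cfg, n=panel.n_individuals)
    return GenePairBlock(gs.gene.gene_id, gt.gene.gene_id, shrunk,
                         np.array(idx_s), np.array(idx_t))
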