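"""End-to-end drivers composing the module steps.

``gene_analysis`` takes harmonized-or-raw summary statistics to a
gene-statistic table plus the gene-gene correlation matrix;
``enrichment_analysis`` continues to the per-cell-type GLS table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import gwas_io
from .enrich import dfbetas_influence, enrich_scan, make_enrichment_input
from .expression import CellTypeExpression
from .gene_assoc import gene_scan, gene_stats_table
from .gene_corr import GeneCorrMatrix, build_gene_corr
from .ld_panel import GenotypePanel, PanelLdProvider, PoetConfig


@dataclass
class AnalysisResult:
    gene_stats: pd.DataFrame
    gene_corr: GeneCorrMatrix
    annotated: list
    enrichment: pd.DataFrame | None = None
    influence: dict = field(default_factory=dict)


def annotate_and_prune(sumstats: pd.DataFrame, panel: GenotypePanel,
                       gene_models, up: int = 10_000, down: int = 1_500,
                       maf_cutoff: float = 0.01, mac_min: int = 20,
                       r2_max: float = 0.8, cap: int = 200,
                       harmonize: bool = True, drop_mhc: bool = True) -> list:
    """QC, harmonize, window-assign, classify, and LD-prune SNPs."""
    stats = sumstats
    if harmonize:
        panel_vars = panel.variants.rename(columns=str)
        stats = gwas_io.harmonize_alleles(stats, panel_vars)
    if drop_mhc:
        stats = gwas_io.filter_mhc(stats)
    annotated = gwas_io.assign_snps_to_genes(stats, gene_models, up=up, down=down)
    provider = PanelLdProvider(panel)
    out = []
    for g in annotated:
        g = gwas_io.classify_by_maf(g, maf_cutoff=maf_cutoff, mac_min=mac_min)
        if g.n_common:
            g = gwas_io.ld_prune(g, provider, r2_max=r2_max, cap=cap)
        if g.n_common or (g.n_rare and not g.rare_skipped):
            out.append(g)
    return out


def gene_analysis(sumstats: pd.DataFrame, panel: GenotypePanel, gene_models,
                  mode: str = "common", d: int = 10,
                  max_dist: int = 5_000_000, poet_cfg: PoetConfig | None = None,
                  n_jobs: int = 1, **qc_kwargs) -> AnalysisResult:
    """Gene-level statistics and the sparse gene-gene correlation matrix."""
    annotated = annotate_and_prune(sumstats, panel, gene_models, **qc_kwargs)
    stats = gene_scan(annotated, panel, mode=mode, cfg=poet_cfg, n_jobs=n_jobs)
    tested = {s.gene_id for s in stats}
    kept = [g for g in annotated if g.gene.gene_id in tested and g.n_common > 0]
    gc = build_gene_corr(kept, panel, d=d, max_dist=max_dist, cfg=poet_cfg,
                         include_pseudo=(mode == "joint"))
    return AnalysisResult(gene_stats_table(stats), gc, annotated)


def enrichment_analysis(result: AnalysisResult, expr: CellTypeExpression,
                        influence_for: str | None = None) -> AnalysisResult:
    """GLS cell-type scan (and optional influence analysis) on a
    completed gene-level analysis."""
    inp = make_enrichment_input(result.gene_stats, expr, result.gene_corr)
    result.enrichment = enrich_scan(inp)
    if influence_for == "top":
        influence_for = result.enrichment.iloc[0]["cell_type"]
    if influence_for:
        result.influence[influence_for] = dfbetas_influence(inp, influence_for)
    return result
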