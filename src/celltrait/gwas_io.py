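"""Ingest and harmonize GWAS summary statistics; annotate SNPs to genes.

The summary-statistic table is a plain :class:`pandas.DataFrame` with
canonical columns ``variant_id, chrom, pos, effect_allele, other_allele,
beta, se, z, p, n, maf``. All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default mapping canonical name -> column name in the input file
DEFAULT_COLUMN_MAP = {
    "variant_id": "SNP", "chrom": "CHR", "pos": "BP",
    "effect_allele": "A1", "other_allele": "A2",
    "beta": "BETA", "se": "SE", "p": "P", "n": "N", "maf": "MAF", "z": "Z",
}

AUTOSOMES = {str(i) for i in range(1, 23)}

#: strand-ambiguous allele pairs (indistinguishable from their complement)
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: default MHC exclusion interval, GRCh37 convention
MHC_REGION = ("6", 25_000_000, 35_000_000)


class ConfigurationError(ValueError):
    pass


class EmptyInputError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """A gene body interval; ``start <= end``, 1-based inclusive."""
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    def window(self, up: int = 10_000, down: int = 1_500) -> tuple[int, int]:
        """Flanked gene window; upstream extends 5' of the gene body.

        Unknown strand is treated as '+'.
        """
        if self.strand == "-":
            return self.start - down, self.end + up
        return self.start - up, self.end + down


@dataclass
class AnnotatedGene:
    """SNPs assigned to one gene window, split into common and rare sets."""
    gene: GeneModel
    common_snps: pd.DataFrame
    rare_snps: pd.DataFrame = field(default_factory=pd.DataFrame)
    mac_rare: float = 0.0
    rare_skipped: bool = False

    @property
    def n_common(self) -> int:
        return len(self.common_snps)

    @property
    def n_rare(self) -> int:
        return len(self.rare_snps)


def _normalize_chrom(c) -> str:
    s = str(c).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def read_summary_stats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a delimited summary-statistic file into the canonical table.

    ``column_map`` maps canonical names to file column names; unmapped
    optional fields are filled with NaN. Requires at minimum a variant
    id, both alleles, and either (beta, se) or z. Keeps autosomes only
    and drops rows with missing or invalid mandatory fields, logging
    the dropped count.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=r"\s+")
    mandatory = ["variant_id", "effect_allele", "other_allele"]
    for name in mandatory:
        if cmap.get(name) not in raw.columns:
            raise ConfigurationError(f"mandatory column {name!r} (mapped to "
                                     f"{cmap.get(name)!r}) not found in {path}")
    have = {k: v for k, v in cmap.items() if v in raw.columns}
    has_beta_se = "beta" in have and "se" in have
    if not has_beta_se and "z" not in have:
        raise ConfigurationError("need either (beta, se) or z columns")
    df = raw[[have[k] for k in have]].copy()
    df.columns = list(have)
    for col in ["chrom", "pos", "beta", "se", "z", "p", "n", "maf"]:
        if col not in df.columns:
            df[col] = np.nan
    n_in = len(df)
    df["chrom"] = df["chrom"].map(_normalize_chrom)
    for col in ["pos", "beta", "se", "z", "p", "n", "maf"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    # fold allele frequencies > 0.5 to minor allele frequencies
    high = df["maf"] > 0.5
    if high.any():
        logger.info("folding %d allele frequencies > 0.5 to MAF", int(high.sum()))
        df.loc[high, "maf"] = 1.0 - df.loc[high, "maf"]

    keep = df["chrom"].isin(AUTOSOMES)
    keep &= df["variant_id"].notna()
    keep &= df["effect_allele"].notna() & df["other_allele"].notna()
    if has_beta_se:
        keep &= df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
    else:
        keep &= df["z"].notna()
    df = df[keep].copy()
    if has_beta_se:
        df["z"] = df["beta"] / df["se"]
    for col in ["effect_allele", "other_allele"]:
        df[col] = df[col].str.upper()
    df["pos"] = df["pos"].astype("Int64")
    n_drop = n_in - len(df)
    if n_drop:
        logger.info("read_summary_stats: dropped %d of %d rows", n_drop, n_in)
    if len(df) == 0:
        raise EmptyInputError(f"no valid summary-statistic rows retained from {path}")
    order = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
             "beta", "se", "z", "p", "n", "maf"]
    return df[order].reset_index(drop=True)


def read_panel_variants(path: str) -> pd.DataFrame:
    """Variant metadata (chrom, pos, ref, alt) from a PLINK .bim or VCF.

    For .bim input the A1 allele is taken as the counting (alt) allele,
    matching the dosage convention of :mod:`celltrait.plink`.
    """
    if path.endswith(".bim"):
        from . import plink
        bim = plink.read_bim(path)
        out = pd.DataFrame({
            "variant_id": bim["variant_id"],
            "chrom": bim["chrom"].map(_normalize_chrom),
            "pos": bim["pos"].astype(int),
            "ref": bim["a2"].str.upper(),
            "alt": bim["a1"].str.upper(),
        })
        return out
    # VCF path
    import cyvcf2
    rows = []
    for v in cyvcf2.VCF(path):
        rows.append((v.ID or f"{v.CHROM}:{v.POS}", _normalize_chrom(v.CHROM),
                     v.POS, v.REF.upper(), v.ALT[0].upper() if v.ALT else "N"))
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])


def harmonize_alleles(stats: pd.DataFrame, panel_variants: pd.DataFrame) -> pd.DataFrame:
    """Align effect alleles to the panel's counting (alt) allele.

    SNPs absent from the panel are removed; where the effect/other
    alleles are swapped relative to the panel, beta and z change sign
    and the allele columns are swapped so the operation is idempotent.
    Strand-ambiguous (A/T, C/G) SNPs and SNPs whose allele pair cannot
    be reconciled with the panel are dropped and logged.
    """
    panel = panel_variants.drop_duplicates(subset=["chrom", "pos"]).set_index(["chrom", "pos"])
    merged = stats.join(panel[["ref", "alt"]], on=["chrom", "pos"], how="inner")
    n_absent = len(stats) - len(merged)

    ea, oa = merged["effect_allele"], merged["other_allele"]
    ambiguous = pd.Series(list(zip(ea, oa)), index=merged.index).isin(AMBIGUOUS_PAIRS)
    aligned = (ea == merged["alt"]) & (oa == merged["ref"])
    swapped = (ea == merged["ref"]) & (oa == merged["alt"])
    keep = (aligned | swapped) & ~ambiguous
    n_mismatch = int((~(aligned | swapped) & ~ambiguous).sum())
    if n_absent or n_mismatch or ambiguous.any():
        logger.info("harmonize_alleles: %d not in panel, %d ambiguous, %d irreconcilable",
                    n_absent, int(ambiguous.sum()), n_mismatch)
    out = merged[keep].copy()
    flip = swapped[keep]
    out.loc[flip, ["beta", "z"]] *= -1.0
    out.loc[flip, "effect_allele"] = out.loc[flip, "alt"]
    out.loc[flip, "other_allele"] = out.loc[flip, "ref"]
    return out.drop(columns=["ref", "alt"]).reset_index(drop=True)


def filter_mhc(stats: pd.DataFrame, region: tuple = MHC_REGION) -> pd.DataFrame:
    """Remove SNPs inside the MHC interval (default chr6:25-35 Mb)."""
    chrom, lo, hi = region
    inside = (stats["chrom"] == _normalize_chrom(chrom)) & \
        (stats["pos"] >= lo) & (stats["pos"] <= hi)
    if inside.any():
        logger.info("filter_mhc: removed %d SNPs", int(inside.sum()))
    return stats[~inside].reset_index(drop=True)


def read_gene_models(path: str) -> list[GeneModel]:
    """Gene models from a GTF (gene features) or a 4+-column BED file.

    BED intervals are 0-based half-open and converted to 1-based
    inclusive coordinates.
    """
    if path.endswith((".gtf", ".gtf.gz")):
        genes = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] != "gene":
                    continue
                attrs = dict(
                    (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                    for kv in parts[8].rstrip(";").split(";") if " " in kv.strip()
                )
                gid = attrs.get("gene_id", f"{parts[0]}:{parts[3]}")
                strand = parts[6] if parts[6] in "+-" else "+"
                genes.append(GeneModel(gid, _normalize_chrom(parts[0]),
                                       int(parts[3]), int(parts[4]), strand))
        return genes
    bed = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if bed.shape[1] < 4:
        raise ConfigurationError("BED gene models need at least 4 columns")
    genes = []
    for row in bed.itertuples(index=False):
        strand = row[5] if bed.shape[1] >= 6 and str(row[5]) in "+-" else "+"
        genes.append(GeneModel(str(row[3]), _normalize_chrom(row[0]),
                               int(row[1]) + 1, int(row[2]), strand))
    return genes


def assign_snps_to_genes(stats: pd.DataFrame, genes: list[GeneModel],
                         up: int = 10_000, down: int = 1_500) -> list[AnnotatedGene]:
    """Assign each SNP to every gene whose flanked window contains it.

    A SNP inside overlapping windows is assigned to all of them; genes
    with zero SNPs are omitted. The returned genes are ordered by
    (chromosome, start).
    """
    if not genes:
        raise ConfigurationError("empty gene list")
    out = []
    by_chrom = {c: g.sort_values("pos") for c, g in stats.groupby("chrom")}
    for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        chrom_stats = by_chrom.get(gene.chrom)
        if chrom_stats is None:
            continue
        lo, hi = gene.window(up, down)
        pos = chrom_stats["pos"].to_numpy()
        i0, i1 = np.searchsorted(pos, [lo, hi + 1])
        if i1 > i0:
            out.append(AnnotatedGene(gene, chrom_stats.iloc[i0:i1].reset_index(drop=True)))
    return out


def classify_by_maf(gene: AnnotatedGene, maf_cutoff: float = 0.01,
                    mac_min: int = 20) -> AnnotatedGene:
    """Split a gene's SNPs into common (maf >= cutoff) and rare sets.

    SNPs with maf = 0 (or missing maf) are dropped. The rare set's
    total minor allele count is 2*n*maf summed over rare SNPs; if it
    does not exceed ``mac_min`` the rare set is emptied and the gene
    flagged so rare-variant testing is skipped.
    """
    snps = pd.concat([gene.common_snps, gene.rare_snps], ignore_index=True)
    maf = snps["maf"]
    common = snps[maf >= maf_cutoff].reset_index(drop=True)
    rare = snps[(maf > 0) & (maf < maf_cutoff)].reset_index(drop=True)
    mac = float(np.nansum(2.0 * rare["n"].to_numpy(dtype=float)
                          * rare["maf"].to_numpy(dtype=float))) if len(rare) else 0.0
    skipped = not mac > mac_min
    if skipped and len(rare):
        rare = rare.iloc[0:0]
    return AnnotatedGene(gene.gene, common, rare, mac_rare=mac, rare_skipped=skipped)


def ld_prune(gene: AnnotatedGene, ld, r2_max: float = 0.8, cap: int = 200,
             window: int = 50, step: int = 5) -> AnnotatedGene:
    """Greedy sliding-window LD pruning of a gene's common SNPs.

    Within successive windows of ``window`` SNPs advanced by ``step``,
    any pair with r² exceeding ``r2_max`` loses its later-position
    member. If more than ``cap`` SNPs survive, pruning is repeated at
    descending thresholds 0.7, 0.6, ... 0.1; if still over the cap, the
    ``cap`` SNPs with largest MAF are kept (positions break ties).

    ``ld`` provides pairwise correlations: either a callable mapping an
    ordered list of variant ids to a correlation matrix, or an object
    with a ``.corr(ids)`` method.
    """
    snps = gene.common_snps.sort_values("pos").reset_index(drop=True)
    if len(snps) <= 1:
        return replace(gene, common_snps=snps)
    ids = list(snps["variant_id"])
    corr_fn = ld.corr if hasattr(ld, "corr") else ld
    r2 = np.asarray(corr_fn(ids), dtype=float) ** 2

    def greedy(alive: np.ndarray, thr: float) -> np.ndarray:
        alive = alive.copy()
        k = len(alive)
        for start in range(0, max(k - 1, 1), step):
            idx = np.flatnonzero(alive[start:start + window]) + start
            for a, i in enumerate(idx):
                if not alive[i]:
                    continue
                for j in idx[a + 1:]:
                    if alive[j] and r2[i, j] > thr:
                        alive[j] = False
        return alive

    alive = greedy(np.ones(len(snps), dtype=bool), r2_max)
    thr = 0.7
    while alive.sum() > cap and thr >= 0.05:
        alive = greedy(alive, thr)
        thr -= 0.1
    if alive.sum() > cap:
        surv = np.flatnonzero(alive)
        order = sorted(surv, key=lambda i: (-snps["maf"].iloc[i], snps["pos"].iloc[i]))
        alive = np.zeros(len(snps), dtype=bool)
        alive[sorted(order[:cap])] = True
    return replace(gene, common_snps=snps[alive].reset_index(drop=True))
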