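import numpy as np
import pandas as pd
import pytest

from celltrait.gwas_io import AnnotatedGene, GeneModel
from celltrait.ld_panel import GenotypePanel
from celltrait.simulate import SimConfig, synth_panel


def make_sumstats(rows):
    """Build a canonical summary-stat frame from dict rows with defaults."""
    defaults = dict(effect_allele="G", other_allele="A", beta=0.1, se=0.1,
                    p=0.5, n=1000, maf=0.2)
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults, variant_id=f"rs{i}", **r)
        d.setdefault("z", d["beta"] / d["se"])
        full.append(d)
    return pd.DataFrame(full)[["variant_id", "chrom", "pos", "effect_allele",
                               "other_allele", "beta", "se", "z", "p", "n", "maf"]]


@pytest.fixture(scope="session")
def small_panel() -> GenotypePanel:
    """500 individuals, 10 genes x 8 SNPs with AR(1) LD."""
    return synth_panel(SimConfig(seed=11, n_genes=10, n_snps_per_gene=8,
                                 n_individuals=500))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def annotated_gene(panel, gene_index, stats=None):
    """AnnotatedGene for one synthetic panel block, z drawn N(0,1) if
    no stats are supplied."""
    gm: GeneModel = panel.meta["gene_models"][gene_index]
    mask = panel.variants["variant_id"].str.startswith(gm.gene_id + "_")
    var = panel.variants[mask]
    rng = np.random.default_rng(100 + gene_index)
    snps = pd.DataFrame({
        "variant_id": var["variant_id"].to_numpy(),
        "chrom": var["chrom"].to_numpy(),
        "pos": var["pos"].to_numpy(),
        "effect_allele": "G", "other_allele": "A",
        "se": 0.1, "z": rng.standard_normal(mask.sum()),
        "n": 1000, "maf": panel.maf(list(var["variant_id"])),
    })
    snps["beta"] = snps["z"] * snps["se"]
    return AnnotatedGene(gm, snps)
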