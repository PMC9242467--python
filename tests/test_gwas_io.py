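"""Summary-statistic ingestion, harmonization, windows, and pruning."""

import numpy as np
import pandas as pd
import pytest

from celltrait import gwas_io
from celltrait.gwas_io import (AnnotatedGene, ConfigurationError, GeneModel,
                               assign_snps_to_genes, classify_by_maf,
                               filter_mhc, harmonize_alleles, ld_prune,
                               read_gene_models, read_summary_stats)

from conftest import make_sumstats


def write_sumstats(tmp_path, df, name="ss.tsv"):
    p = tmp_path / name
    df.to_csv(p, sep="\t", index=False)
    return str(p)


class TestReadSummaryStats:
    def test_autosome_filter_and_z_from_beta_se(self, tmp_path):
        raw = pd.DataFrame({
            "SNP": ["rs1", "rs2", "rs3"], "CHR": ["1", "X", "2"],
            "BP": [100, 200, 300], "A1": ["A", "C", "G"], "A2": ["G", "T", "A"],
            "BETA": [0.2, 0.1, -0.3], "SE": [0.1, 0.1, 0.15], "N": 100,
        })
        out = read_summary_stats(write_sumstats(tmp_path, raw))
        assert list(out["variant_id"]) == ["rs1", "rs3"]  # X dropped
        np.testing.assert_allclose(out["z"], [2.0, -2.0])

    def test_zero_se_row_dropped(self, tmp_path):
        raw = pd.DataFrame({
            "SNP": ["rs1", "rs2"], "CHR": "1", "BP": [1, 2],
            "A1": "A", "A2": "G", "BETA": [0.1, 0.1], "SE": [0.0, 0.1],
        })
        out = read_summary_stats(write_sumstats(tmp_path, raw))
        assert list(out["variant_id"]) == ["rs2"]

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        raw = pd.DataFrame({"SNP": ["rs1"], "CHR": "1", "BP": [1],
                            "A1": "A", "A2": "G"})
        with pytest.raises(ConfigurationError):
            read_summary_stats(write_sumstats(tmp_path, raw))

    def test_all_rows_invalid_is_empty_input_error(self, tmp_path):
        raw = pd.DataFrame({"SNP": ["rs1"], "CHR": "X", "BP": [1],
                            "A1": "A", "A2": "G", "BETA": [0.1], "SE": [0.1]})
        with pytest.raises(gwas_io.EmptyInputError):
            read_summary_stats(write_sumstats(tmp_path, raw))

    def test_custom_column_map(self, tmp_path):
        raw = pd.DataFrame({"id": ["rs1"], "chr": "3", "position": [5],
                            "ea": "A", "oa": "G", "zscore": [1.5]})
        out = read_summary_stats(write_sumstats(tmp_path, raw), column_map={
            "variant_id": "id", "chrom": "chr", "pos": "position",
            "effect_allele": "ea", "other_allele": "oa", "z": "zscore"})
        assert out.loc[0, "z"] == 1.5


class TestHarmonize:
    panel = pd.DataFrame({
        "variant_id": ["rs1", "rs2", "rs3", "rs4"], "chrom": "1",
        "pos": [100, 200, 300, 400],
        "ref": ["A", "A", "A", "A"], "alt": ["G", "G", "T", "C"],
    })

    def test_aligned_swapped_ambiguous_mismatched(self):
        ss = make_sumstats([
            dict(chrom="1", pos=100, effect_allele="G", other_allele="A", z=2.0),
            dict(chrom="1", pos=200, effect_allele="A", other_allele="G", z=2.0),
            dict(chrom="1", pos=300, effect_allele="A", other_allele="T", z=2.0),
            dict(chrom="1", pos=400, effect_allele="A", other_allele="G", z=2.0),
            dict(chrom="1", pos=999, effect_allele="A", other_allele="G", z=2.0),
        ])
        out = harmonize_alleles(ss, self.panel)
        # aligned kept as-is; swapped sign-flipped; ambiguous A/T dropped;
        # irreconcilable pair dropped; absent-from-panel dropped
        assert len(out) == 2
        assert out.loc[out["pos"] == 100, "z"].iloc[0] == 2.0
        assert out.loc[out["pos"] == 200, "z"].iloc[0] == -2.0

    def test_idempotence(self):
        ss = make_sumstats([
            dict(chrom="1", pos=100, effect_allele="G", other_allele="A", z=1.0),
            dict(chrom="1", pos=200, effect_allele="A", other_allele="G", z=1.0),
        ])
        once = harmonize_alleles(ss, self.panel)
        twice = harmonize_alleles(once, self.panel)
        pd.testing.assert_frame_equal(once, twice)


def test_filter_mhc_default_interval():
    ss = make_sumstats([
        dict(chrom="6", pos=30_000_000),
        dict(chrom="6", pos=40_000_000),
        dict(chrom="1", pos=30_000_000),
    ])
    out = filter_mhc(ss)
    assert set(zip(out["chrom"], out["pos"])) == {("6", 40_000_000),
                                                  ("1", 30_000_000)}


class TestAssignSnpsToGenes:
    genes = [GeneModel("gA", "1", 100_000, 105_000, "+"),
             GeneModel("gB", "1", 104_000, 110_000, "+"),
             GeneModel("gC", "2", 100_000, 105_000, "-")]

    def test_window_boundaries_plus_strand(self):
        # +-strand window [90,000, 106,500]
        ss = make_sumstats([
            dict(chrom="1", pos=95_000), dict(chrom="1", pos=89_999),
            dict(chrom="1", pos=90_000), dict(chrom="1", pos=106_500),
            dict(chrom="1", pos=106_501),
        ])
        out = assign_snps_to_genes(ss, [self.genes[0]])
        assert sorted(out[0].common_snps["pos"]) == [90_000, 95_000, 106_500]

    def test_minus_strand_upstream_beyond_end(self):
        # --strand: window [start-1500, end+10000] = [98,500, 115,000]
        ss = make_sumstats([dict(chrom="2", pos=112_000),
                            dict(chrom="2", pos=93_000)])
        out = assign_snps_to_genes(ss, [self.genes[2]])
        assert list(out[0].common_snps["pos"]) == [112_000]

    def test_multi_assignment_and_reversibility(self):
        ss = make_sumstats([dict(chrom="1", pos=104_500),
                            dict(chrom="1", pos=300_000)])
        out = assign_snps_to_genes(ss, self.genes)
        names = [a.gene.gene_id for a in out]
        assert names == ["gA", "gB"]
        for a in out:
            lo, hi = a.gene.window()
            assert ((a.common_snps["pos"] >= lo) & (a.common_snps["pos"] <= hi)).all()

    def test_empty_gene_list_rejected(self):
        ss = make_sumstats([dict(chrom="1", pos=1)])
        with pytest.raises(ConfigurationError):
            assign_snps_to_genes(ss, [])


class TestClassifyByMaf:
    def make_gene(self, mafs, n=10_000):
        ss = make_sumstats([dict(chrom="1", pos=100 + i, maf=m, n=n)
                            for i, m in enumerate(mafs)])
        return AnnotatedGene(GeneModel("g", "1", 50, 200), ss)

    def test_boundary_and_partition(self):
        mafs = [0.005, 0.01, 0.3, 0.0, 0.009]
        out = classify_by_maf(self.make_gene(mafs))
        assert out.n_common == 2  # 0.01 boundary goes common
        assert out.n_rare == 2
        n_dropped = 1  # maf == 0
        assert out.n_common + out.n_rare + n_dropped == len(mafs)

    def test_mac_gate_is_strict(self):
        # single rare SNP with 2*n*maf == 20 exactly -> rare set skipped
        out = classify_by_maf(self.make_gene([0.005, 0.3], n=2000))
        assert out.mac_rare == pytest.approx(20.0)
        assert out.rare_skipped and out.n_rare == 0
        # mac 22 > 20 -> kept
        out2 = classify_by_maf(self.make_gene([0.0055, 0.3], n=2000))
        assert out2.n_rare == 1 and not out2.rare_skipped


class TestLdPrune:
    def prune(self, r2, mafs=None, **kw):
        K = r2.shape[0]
        mafs = mafs if mafs is not None else [0.2] * K
        ss = make_sumstats([dict(chrom="1", pos=100 + i, maf=mafs[i])
                            for i in range(K)])
        gene = AnnotatedGene(GeneModel("g", "1", 1, 1000), ss)
        out = ld_prune(gene, lambda ids: np.sqrt(r2), **kw)
        return [int(p) - 100 for p in out.common_snps["pos"]]

    def test_independent_snps_all_kept(self):
        assert self.prune(np.eye(4)) == [0, 1, 2, 3]

    def test_duplicate_pair_keeps_earlier(self):
        r2 = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert self.prune(r2) == [0]

    def test_greedy_three_snp_chain(self):
        # r2(1,2)=r2(2,3)=0.9, r2(1,3)=0.64: greedy removes SNP 2 only
        r2 = np.array([[1.0, 0.9, 0.64], [0.9, 1.0, 0.9], [0.64, 0.9, 1.0]])
        assert self.prune(r2) == [0, 2]

    def test_no_surviving_pair_exceeds_threshold(self, small_panel):
        from celltrait.ld_panel import PanelLdProvider
        from conftest import annotated_gene
        gene = annotated_gene(small_panel, 0)
        provider = PanelLdProvider(small_panel)
        out = ld_prune(gene, provider, r2_max=0.1)
        ids = list(out.common_snps["variant_id"])
        r2 = provider.corr(ids) ** 2
        np.fill_diagonal(r2, 0)
        assert r2.max() <= 0.1 + 1e-12

    def test_cap_by_descending_thresholds_then_maf(self):
        # 6 mutually independent SNPs, cap 3: thresholds cannot prune, so
        # the 3 largest-MAF SNPs survive in position order
        mafs = [0.1, 0.4, 0.2, 0.5, 0.3, 0.05]
        assert self.prune(np.eye(6), mafs=mafs, cap=3) == [1, 3, 4]


def test_read_gene_models_bed_and_gtf(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("chr1\t999\t2000\tgeneA\t0\t-\n1\t10\t20\tgeneB\n")
    models = read_gene_models(str(bed))
    assert models[0] == GeneModel("geneA", "1", 1000, 2000, "-")
    assert models[1] == GeneModel("geneB", "1", 11, 20, "+")
    gtf = tmp_path / "genes.gtf"
    gtf.write_text('1\tsrc\tgene\t1000\t2000\t.\t+\t.\tgene_id "G1"; gene_name "x";\n'
                   '1\tsrc\texon\t1000\t1100\t.\t+\t.\tgene_id "G1";\n')
    models = read_gene_models(str(gtf))
    assert models == [GeneModel("G1", "1", 1000, 2000, "+")]
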