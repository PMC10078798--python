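"""Regulatory domains, proximity windows, and retention filters."""

import numpy as np
import pandas as pd
import pytest

from odontoprio.enhancer_extraction import EnhancerSet
from odontoprio.gene_association import (
    assign_enhancers_to_genes,
    build_regulatory_domains,
    filter_de_genes,
    filter_gwas_variants,
    genes_near_intervals,
    genes_near_variants,
)
from odontoprio.genomic_core import GeneRecord, GenomicInterval, VariantRecord, merge_intervals

from _oracles import allpairs_assignment_counts

GI = GenomicInterval
SIZES = {"chr1": 10_000_000, "chr2": 10_000_000}


def gene(gid, tss, strand="+", chrom="chr1", length=10_000):
    if strand == "+":
        return GeneRecord(gid, gid.upper(), chrom, tss, tss + length, "+")
    return GeneRecord(gid, gid.upper(), chrom, tss - length + 1, tss + 1, "-")


class TestRegulatoryDomains:
    def test_single_plus_gene_basal_and_extension(self):
        doms = build_regulatory_domains([gene("g1", 2_000_000)], SIZES)
        d = doms[0]
        assert (d.basal.start, d.basal.end) == (1_995_000, 2_001_000)
        assert (d.extended.start, d.extended.end) == (995_000, 3_001_000)

    def test_neighbor_truncates_upstream_extension(self):
        g1, g2 = gene("g1", 1_000_000), gene("g2", 1_010_000)
        doms = {d.gene_id: d for d in build_regulatory_domains([g1, g2], SIZES)}
        # gene2's upstream extension stops at gene1's basal edge
        assert doms["g2"].extended.start == 1_001_000
        # and gene1's downstream extension stops at gene2's basal edge
        assert doms["g1"].extended.end == 1_005_000

    def test_clipped_at_chromosome_start(self):
        d = build_regulatory_domains([gene("g1", 500)], SIZES)[0]
        assert d.basal.start == 0 and d.extended.start == 0

    def test_minus_strand_basal_is_mirrored(self):
        d = build_regulatory_domains([gene("g1", 2_000_000, strand="-")], SIZES)[0]
        assert (d.basal.start, d.basal.end) == (1_999_000, 2_005_000)

    def test_missing_chrom_errors(self):
        with pytest.raises(ValueError, match="chrom_sizes"):
            build_regulatory_domains([gene("g1", 100, chrom="chrZ")], {"chr1": 1000})

    def test_zero_extension_collapses_to_basal(self):
        genes = [gene("g1", 1_000_000), gene("g2", 1_400_000, strand="-")]
        for d in build_regulatory_domains(genes, SIZES, max_extension=0):
            assert (d.extended.start, d.extended.end) == (d.basal.start, d.basal.end)

    def test_identical_tss_do_not_truncate_each_other(self):
        g1 = GeneRecord("g1", "G1", "chr1", 2_000_000, 2_010_000, "+")
        g2 = GeneRecord("g2", "G2", "chr1", 2_000_000, 2_005_000, "+")
        doms = {d.gene_id: d for d in build_regulatory_domains([g1, g2], SIZES)}
        assert doms["g1"].extended.start == 995_000
        assert doms["g2"].extended.start == 995_000


class TestEnhancerAssignment:
    def test_single_and_multi_assignment(self):
        genes = [gene("g1", 1_000_000), gene("g2", 1_010_000)]
        doms = build_regulatory_domains(genes, SIZES)
        inside_one = EnhancerSet("t", "strong", [GI("chr1", 999_000, 999_200)])
        counts = assign_enhancers_to_genes(inside_one, doms).counts()
        assert counts == {"g1": 1}
        # intergenic enhancer between the basal domains sits in both extensions
        between = EnhancerSet("t", "strong", [GI("chr1", 1_002_000, 1_002_200)])
        assert assign_enhancers_to_genes(between, doms).counts() == {"g1": 1, "g2": 1}

    def test_counts_match_allpairs_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            genes = [
                gene(f"g{i}", int(rng.integers(100_000, 9_000_000)),
                     strand="+-"[i % 2], chrom=f"chr{1 + i % 2}")
                for i in range(5)
            ]
            doms = build_regulatory_domains(genes, SIZES)
            ivs = merge_intervals(
                [
                    GI(f"chr{1 + int(rng.integers(2))}",
                       int(s := rng.integers(0, 9_990_000)),
                       int(s) + int(rng.integers(100, 5_000)))
                    for _ in range(50)
                ]
            )
            es = EnhancerSet("t", "strong", ivs)
            got = assign_enhancers_to_genes(es, doms)
            assert got.counts() == allpairs_assignment_counts(ivs, doms)
            assert got.n_links() == sum(allpairs_assignment_counts(ivs, doms).values())

    def test_signed_distance_is_midpoint_minus_tss(self):
        genes = [gene("g1", 1_000_000)]
        doms = build_regulatory_domains(genes, SIZES)
        es = EnhancerSet("t", "strong", [GI("chr1", 900_000, 900_200)])
        links = assign_enhancers_to_genes(es, doms).links
        assert links.distance.tolist() == [900_100 - 1_000_000]


class TestProximityWindows:
    def test_variant_inside_gene_body(self):
        g = [gene("g1", 1_000_000)]
        v = [VariantRecord("rs1", "chr1", 1_005_000, 1e-9)]
        assert genes_near_variants(g, v) == {"g1"}

    def test_window_boundary_inclusive(self):
        g = [gene("g1", 1_000_000)]  # span [1_000_000, 1_010_000)
        at = VariantRecord("rs1", "chr1", 1_009_999 + 500_000, 1e-9)
        beyond = VariantRecord("rs2", "chr1", 1_009_999 + 500_001, 1e-9)
        assert genes_near_variants(g, [at]) == {"g1"}
        assert genes_near_variants(g, [beyond]) == set()

    def test_other_chrom_excluded(self):
        g = [gene("g1", 1_000_000)]
        v = [VariantRecord("rs1", "chr2", 1_005_000, 1e-9)]
        assert genes_near_variants(g, v) == set()

    def test_tss_anchor(self):
        g = [gene("g1", 1_000_000)]
        v = [VariantRecord("rs1", "chr1", 1_500_000, 1e-9)]
        assert genes_near_variants(g, v, anchor="tss") == {"g1"}
        v2 = [VariantRecord("rs1", "chr1", 1_500_001, 1e-9)]
        assert genes_near_variants(g, v2, anchor="tss") == set()

    def test_window_monotonicity(self):
        rng = np.random.default_rng(31)
        genes = [gene(f"g{i}", int(rng.integers(100_000, 9_000_000))) for i in range(10)]
        vars_ = [
            VariantRecord(f"rs{i}", "chr1", int(rng.integers(0, 10_000_000)), 1e-9)
            for i in range(10)
        ]
        prev: set = set()
        for w in (0, 10_000, 100_000, 500_000, 2_000_000):
            cur = genes_near_variants(genes, vars_, window=w)
            assert prev <= cur
            prev = cur

    def test_interval_window_boundaries(self):
        g = [gene("g1", 2_000_000)]  # span [2_000_000, 2_010_000)
        at = GI("chr1", 999_000, 1_000_000)  # gap exactly 1_000_000
        beyond = GI("chr1", 998_999, 999_999)  # gap 1_000_001
        overlapping = GI("chr1", 2_005_000, 2_006_000)
        assert genes_near_intervals(g, [at]) == {"g1"}
        assert genes_near_intervals(g, [beyond]) == set()
        assert genes_near_intervals(g, [overlapping]) == {"g1"}
        assert genes_near_intervals(g, []) == set()


class TestRetentionFilters:
    def test_gwas_alpha_inclusive(self):
        keep = VariantRecord("rs1", "chr1", 10, 5e-8, "odontogenesis")
        drop = VariantRecord("rs2", "chr1", 20, 6e-8, "odontogenesis")
        assert filter_gwas_variants([keep, drop]) == [keep]

    def test_gwas_trait_filter_and_dedup(self):
        v1 = VariantRecord("rs1", "chr1", 10, 1e-9, "odontogenesis")
        v1_dup = VariantRecord("rs1", "chr1", 10, 1e-9, "odontogenesis")
        v2 = VariantRecord("rs1", "chr1", 500, 1e-9, "odontogenesis")  # multi-mapping
        v3 = VariantRecord("rs3", "chr1", 30, 1e-9, "body height")
        out = filter_gwas_variants([v1, v1_dup, v2, v3], traits={"odontogenesis"})
        assert out == [v1, v2]

    def test_de_filter_boundaries(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2fc": [2.0, 3.1, 2.5],
                "padj": [0.01, 0.05, 0.051],
            }
        )
        # strict > on fold change, inclusive <= on adjusted p
        assert filter_de_genes(df) == {"b"}

    def test_de_filter_schema_and_range_errors(self):
        with pytest.raises(ValueError, match="missing"):
            filter_de_genes(pd.DataFrame({"gene_id": [], "log2fc": []}))
        bad = pd.DataFrame({"gene_id": ["a"], "log2fc": [3.0], "padj": [1.2]})
        with pytest.raises(ValueError, match="padj"):
            filter_de_genes(bad)

    def test_de_filter_empty_table(self):
        df = pd.DataFrame({"gene_id": [], "log2fc": [], "padj": []})
        assert filter_de_genes(df) == set()
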