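"""Variant catalog: region arithmetic, VCF filtering, gene assignment."""

import numpy as np
import pytest

from asebias.catalog import (
    GeneModel,
    RegionSet,
    VariantCatalog,
    VariantSite,
    build_feature_regions,
    load_variants,
    map_sites_to_genes,
    merge_intervals,
    read_gene_models,
)


def write_vcf(path, records):
    """records: (chrom, pos1, id, ref, alt_field)"""
    lines = ["##fileformat=VCFv4.2",
             '##contig=<ID=chr1,length=100000>',
             '##contig=<ID=chr2,length=100000>',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for chrom, pos, vid, ref, alt in records:
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.")
    path.write_text("\n".join(lines) + "\n")


class TestRegions:
    def test_two_exon_gene_regions(self, two_exon_gene):
        regions = build_feature_regions([two_exon_gene], flank=5000)
        assert regions.by_kind("exon") == [("chr1", 1000, 1200), ("chr1", 1800, 2000)]
        assert regions.by_kind("intron") == [("chr1", 1200, 1800)]
        # left flank truncated at 0 (1000 - 5000 < 0), right extends 5 kb
        assert regions.by_kind("flank5k") == [("chr1", 0, 1000), ("chr1", 2000, 7000)]

    def test_single_exon_gene_has_no_introns(self):
        gene = GeneModel("g", "chr1", (100, 200), [(100, 200)])
        regions = build_feature_regions([gene])
        assert regions.by_kind("intron") == []

    def test_left_flank_clamped_at_zero(self):
        gene = GeneModel("g", "chr1", (2, 50), [(2, 50)])
        regions = build_feature_regions([gene], flank=5000)
        assert ("chr1", 0, 2) in regions.by_kind("flank5k")

    def test_membership_matches_bruteforce_oracle(self, rng):
        """Interval arithmetic vs per-base membership on a toy genome."""
        genes = []
        for i in range(5):
            start = int(rng.integers(0, 8000))
            exons = sorted(rng.integers(start, start + 1500, size=4))
            try:
                genes.append(GeneModel(f"g{i}", "chr1", (exons[0], exons[-1] + 10),
                                       [(exons[0], exons[1] + 1),
                                        (exons[2], exons[3] + 1)]))
            except ValueError:
                continue
        flank = 300
        regions = build_feature_regions(genes, flank=flank)
        member = np.zeros(10_000, dtype=bool)
        for gene in genes:
            lo, hi = gene.exons[0][0], gene.exons[-1][1]
            member[max(0, lo - flank):hi + flank] = True
        for pos in range(0, 10_000, 7):
            assert regions.contains("chr1", pos) == bool(member[pos]), pos

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            RegionSet([("chr1", 10, 10, "exon")])

    def test_merge_intervals(self):
        assert merge_intervals([(5, 10), (8, 12), (20, 30)]) == [(5, 12), (20, 30)]


class TestAnnotationReader:
    def test_reads_gff3_and_gtf(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=gene:gA\n"
            "chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tParent=gene:gA\n"
            "chr1\tsrc\texon\t1801\t2000\t.\t+\t.\tParent=gene:gA\n")
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "gA";\n'
            'chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tgene_id "gA";\n'
            'chr1\tsrc\texon\t1801\t2000\t.\t+\t.\tgene_id "gA";\n')
        for path in (gff, gtf):
            (gene,) = read_gene_models(path)
            assert gene.gene_id == "gA"
            assert gene.exons == [(1000, 1200), (1800, 2000)]

    def test_malformed_record_reports_line(self, tmp_path):
        bad = tmp_path / "bad.gff3"
        bad.write_text("chr1\tsrc\tgene\tnotanumber\t2000\t.\t+\t.\tID=g\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gene_models(bad)

    def test_gene_without_exons_skipped_with_warning(self, tmp_path):
        gff = tmp_path / "noexon.gff3"
        gff.write_text("chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=gene:gX\n")
        with pytest.warns(UserWarning, match="gX"):
            assert read_gene_models(gff) == []


class TestLoadVariants:
    def test_filters_by_type_and_region(self, tmp_path, two_exon_gene):
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, [
            ("chr1", 1051, "keep_exonic", "C", "A"),
            ("chr1", 1052, "drop_indel", "CT", "C"),
            ("chr1", 1053, "drop_multi", "A", "G,T"),
            ("chr1", 50_000, "drop_intergenic", "A", "G"),
            ("chr1", 1500, "keep_intronic", "T", "C"),
        ])
        regions = build_feature_regions([two_exon_gene], flank=5000)
        catalog, dropped = load_variants(vcf, regions)
        assert {s.variant_id for s in catalog} == {"keep_exonic", "keep_intronic"}
        assert dropped["indel"] == 1
        assert dropped["multi_allelic"] == 1
        assert dropped["outside_regions"] == 1

    def test_all_sites_overlap_regions_by_requery(self, tmp_path, two_exon_gene):
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, [("chr1", p, f"s{p}", "A", "G")
                        for p in (900, 1100, 1500, 1900, 6000, 7500)])
        regions = build_feature_regions([two_exon_gene], flank=5000)
        catalog, _ = load_variants(vcf, regions)
        assert len(catalog) > 0
        for site in catalog:
            assert regions.contains(site.chrom, site.pos)

    def test_empty_catalog_warns_not_errors(self, tmp_path, two_exon_gene):
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, [("chr2", 99_000, "far", "A", "G")])
        regions = build_feature_regions([two_exon_gene])
        with pytest.warns(UserWarning):
            catalog, _ = load_variants(vcf, regions)
        assert len(catalog) == 0

    def test_vcf_round_trip(self, tmp_path, small_catalog):
        out = tmp_path / "cat.vcf"
        small_catalog.to_vcf(out)
        reloaded, _ = load_variants(out)
        original = {(s.chrom, s.pos, s.ref_allele, s.alt_allele)
                    for s in small_catalog}
        assert {(s.chrom, s.pos, s.ref_allele, s.alt_allele)
                for s in reloaded} == original

    def test_chrom_alias_remapping(self, tmp_path, two_exon_gene):
        vcf = tmp_path / "v.vcf"
        lines = ["##fileformat=VCFv4.2", '##contig=<ID=1,length=100000>',
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
                 "1\t1051\trs1\tC\tA\t.\t.\t."]
        vcf.write_text("\n".join(lines) + "\n")
        regions = build_feature_regions([two_exon_gene])
        catalog, _ = load_variants(vcf, regions, chrom_aliases={"1": "chr1"})
        assert len(catalog) == 1 and catalog.sites[0].chrom == "chr1"


class TestSiteTypes:
    def test_invalid_sites_rejected(self):
        with pytest.raises(ValueError):
            VariantSite("chr1", 10, "A", "A")
        with pytest.raises(ValueError):
            VariantSite("chr1", 10, "AT", "A")
        with pytest.raises(ValueError):
            VariantSite("chr1", -1, "A", "G")

    def test_id_synthesised_from_coordinates(self):
        site = VariantSite("chr1", 99, "A", "G")
        assert site.variant_id == "chr1:100"

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError):
            VariantCatalog([VariantSite("chr1", 5, "A", "G"),
                            VariantSite("chr1", 5, "C", "T")])


class TestGeneAssignment:
    def test_assignment_including_overlap_and_null(self, small_catalog):
        genes = [
            GeneModel("gA", "chr1", (1000, 1200), [(1000, 1200)]),
            GeneModel("gB", "chr1", (1080, 2000), [(1080, 2000)]),
        ]
        gene_of = map_sites_to_genes(small_catalog, genes, flank=0)
        assert gene_of[("chr1", 1050)] == ["gA"]
        assert sorted(gene_of[("chr1", 1100)]) == ["gA", "gB"]  # overlap: both
        assert gene_of[("chr1", 1900)] == ["gB"]
        assert gene_of[("chr2", 500)] == []  # intergenic: null assignment

    def test_flank_extends_assignment(self, small_catalog):
        genes = [GeneModel("gA", "chr1", (1500, 1600), [(1500, 1600)])]
        assert map_sites_to_genes(small_catalog, genes, flank=0)[("chr1", 1100)] == []
        assert map_sites_to_genes(small_catalog, genes, flank=5000)[
            ("chr1", 1100)] == ["gA"]

    def test_exon_only_restriction(self, small_catalog):
        genes = [GeneModel("gA", "chr1", (1000, 2000),
                           [(1000, 1060), (1890, 2000)])]
        gene_of = map_sites_to_genes(small_catalog, genes, exon_only=True)
        assert gene_of[("chr1", 1050)] == ["gA"]
        assert gene_of[("chr1", 1100)] == []  # intronic, excluded by the flag
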