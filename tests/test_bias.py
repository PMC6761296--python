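"""Mapping-bias removal: flipping, remap concordance, unbiased dedup."""

from collections import Counter

import numpy as np
import pytest

from asebias.bias import (
    RemapResult,
    ToyAligner,
    ToyExactAligner,
    dedup_unbiased,
    filter_by_remap,
    make_synthetic_reads,
    overlapped_sites,
    revcomp,
    run_bias_filter,
)
from asebias.catalog import VariantCatalog, VariantSite


class TestIntersect:
    def test_single_site_offset(self, make_read, small_catalog):
        read = make_read("r1", "chr1", 1010, "A" * 125)
        sites = overlapped_sites(read, small_catalog)
        assert [(s.pos, off) for s, off in sites] == [(1050, 40), (1100, 90)]

    def test_site_in_deletion_not_counted(self, make_read, small_catalog):
        # 40M spans 1010-1050, the 15D deletes 1050-1065 (site at 1050), then 60M
        read = make_read("r1", "chr1", 1010, "A" * 100, cigar="40M15D60M")
        sites = overlapped_sites(read, small_catalog)
        assert [(s.pos, off) for s, off in sites] == [(1100, 75)]

    def test_insertion_shifts_offset(self, make_read, small_catalog):
        read = make_read("r1", "chr1", 1040, "A" * 30, cigar="5M10I15M")
        # reference walks 1040..1044 then 1045..1059; site 1050 at qpos 15+5
        sites = overlapped_sites(read, small_catalog)
        assert [(s.pos, off) for s, off in sites] == [(1050, 20)]

    def test_chromosome_absent_from_catalog_is_clean(self, make_read):
        catalog = VariantCatalog([VariantSite("chr2", 5, "A", "G")])
        read = make_read("r1", "chr1", 0, "A" * 50)
        assert overlapped_sites(read, catalog) == []

    def test_three_sites(self, make_read, small_catalog):
        read = make_read("r1", "chr1", 1000, "A" * 1000)
        assert len(overlapped_sites(read, small_catalog)) == 3


class TestSyntheticReads:
    @pytest.mark.parametrize("n", range(1, 7))
    def test_combination_count_is_2_to_n(self, make_read, n):
        sites = [VariantSite("chr1", 100 + i, "A", "G") for i in range(n)]
        catalog = VariantCatalog(sites)
        read = make_read("r1", "chr1", 100, "A" * 50)
        sset = make_synthetic_reads(read, overlapped_sites(read, catalog))
        # original combination counted among 2^n but not re-emitted
        assert len(sset.copies) == 2**n - 1

    def test_copies_differ_only_at_sites(self, make_read):
        catalog = VariantCatalog([VariantSite("chr1", 105, "A", "G"),
                                  VariantSite("chr1", 110, "A", "C")])
        read = make_read("r1", "chr1", 100, "A" * 20)
        sset = make_synthetic_reads(read, overlapped_sites(read, catalog))
        for _, seq in sset.copies:
            diffs = [i for i, (x, y) in enumerate(zip(seq, read.query_sequence))
                     if x != y]
            assert set(diffs) <= {5, 10}
            assert len(diffs) >= 1

    def test_flip_involution(self, make_read):
        """Flipping the same site twice restores the original sequence."""
        catalog = VariantCatalog([VariantSite("chr1", 105, "A", "G")])
        read = make_read("r1", "chr1", 100, "A" * 20)
        sset = make_synthetic_reads(read, overlapped_sites(read, catalog))
        (_, flipped) = sset.copies[0]
        reflip = make_synthetic_reads(make_read("r2", "chr1", 100, flipped),
                                      overlapped_sites(read, catalog))
        assert reflip.copies[0][1] == read.query_sequence

    def test_too_many_sites_discards_read(self, make_read):
        sites = [VariantSite("chr1", 100 + i, "A", "G") for i in range(7)]
        catalog = VariantCatalog(sites)
        read = make_read("r1", "chr1", 100, "A" * 50)
        metrics = Counter()
        assert make_synthetic_reads(read, overlapped_sites(read, catalog),
                                    metrics=metrics) is None
        assert metrics["reads_discarded_too_many_sites"] == 1

    def test_neither_allele_site_skipped(self, make_read):
        catalog = VariantCatalog([VariantSite("chr1", 105, "C", "G")])
        read = make_read("r1", "chr1", 100, "A" * 20)  # base A: neither C nor G
        metrics = Counter()
        sset = make_synthetic_reads(read, overlapped_sites(read, catalog),
                                    metrics=metrics)
        assert sset.copies == []
        assert metrics["sites_skipped_neither_allele"] == 1


class TestRemapFilter:
    def _sset(self, make_read, n=2):
        catalog = VariantCatalog(
            [VariantSite("chr1", 100 + i, "A", "G") for i in range(n)])
        read = make_read("r1", "chr1", 100, "A" * 30)
        return make_synthetic_reads(read, overlapped_sites(read, catalog))

    def test_all_concordant_keeps(self, make_read):
        sset = self._sset(make_read)
        remapped = {name: RemapResult(True, True, "chr1", 100, 30)
                    for name, _ in sset.copies}
        assert filter_by_remap(sset, remapped) is True

    @pytest.mark.parametrize("bad", [
        RemapResult(True, True, "chr2", 100, 30),   # different chromosome
        RemapResult(True, True, "chr1", 250, 30),   # paralogous coordinate
        RemapResult(False),                          # unmapped
        RemapResult(True, False),                    # multi-mapped
    ])
    def test_any_discordant_copy_discards(self, make_read, bad):
        sset = self._sset(make_read)
        remapped = {name: RemapResult(True, True, "chr1", 100, 30)
                    for name, _ in sset.copies}
        remapped[sset.copies[0][0]] = bad
        assert filter_by_remap(sset, remapped) is False

    def test_missing_result_is_hard_error(self, make_read):
        sset = self._sset(make_read)
        with pytest.raises(RuntimeError, match="missing remap"):
            filter_by_remap(sset, {})


class TestToyAligner:
    genome = {"chrA": "ACGTACGTAAGGCCTTACGATCGATCGGGCATTT",
              "chrB": "TTTTTTTTTTGGGGGGGGGG"}

    def test_unique_exact_hit(self):
        res = ToyExactAligner(self.genome)([("q", "AAGGCCTT")])["q"]
        assert res.mapped and res.unique
        assert (res.chrom, res.pos) == ("chrA", 8)

    def test_reverse_strand_hit(self):
        res = ToyExactAligner(self.genome)([("q", revcomp("AAGGCCTT"))])["q"]
        assert res.mapped and res.unique and res.pos == 8

    def test_multihit_reported(self):
        res = ToyExactAligner(self.genome)([("q", "TTTTT")])["q"]
        assert res.mapped and not res.unique

    def test_unmapped(self):
        res = ToyExactAligner(self.genome)([("q", "AACCAACCAACC")])["q"]
        assert not res.mapped

    def test_mismatch_tolerance_prefers_best(self):
        aligner = ToyAligner(self.genome, max_mismatches=2)
        res = aligner([("q", "AAGGCGTT")])["q"]  # 1 mismatch vs chrA:8
        assert res.mapped and res.unique and res.pos == 8

    def test_deterministic(self):
        aligner = ToyAligner(self.genome, max_mismatches=1)
        queries = [("a", "AAGGCCTT"), ("b", "TTTTT"), ("c", "ACGATCGATC")]
        assert aligner(queries) == aligner(queries)


class TestDedup:
    def test_exactly_one_survivor_reproducibly(self, make_read):
        reads = [make_read(f"r{i}", "chr1", 500, "A" * 30) for i in range(3)]
        kept1 = dedup_unbiased(reads, seed=42)
        kept2 = dedup_unbiased(reads, seed=42)
        assert len(kept1) == 1
        assert kept1[0].query_name == kept2[0].query_name

    def test_no_duplicates_unchanged(self, make_read):
        reads = [make_read(f"r{i}", "chr1", 500 + i, "A" * 30) for i in range(4)]
        assert len(dedup_unbiased(reads, seed=0)) == 4

    def test_allele_retention_unbiased(self, make_read):
        """Across seeds, each duplicate allele survives about half the time."""
        reads = [make_read("ref", "chr1", 500, "A" * 30),
                 make_read("alt", "chr1", 500, "A" * 30)]
        n = 10_000
        kept_ref = sum(dedup_unbiased(reads, seed=s)[0].query_name == "ref"
                       for s in range(n))
        # Binomial(10^4, 0.5): 5 sigma is 250
        assert abs(kept_ref - n / 2) < 250


class TestEndToEnd:
    def test_duplicated_segment_discards_ambiguous_reads(self, make_read):
        """Reads whose alt copy matches a paralogous duplicate are discarded;
        reads in unique sequence all survive."""
        rng = np.random.default_rng(1)
        uniq = "".join(rng.choice(list("ACGT"), 400))
        # site at chr1:200 (ref A); the duplicate carries the alt haplotype G
        genome_chr1 = uniq[:200] + "A" + uniq[201:]
        window = uniq[150:200] + "G" + uniq[201:251]
        genome = {"chr1": genome_chr1, "dup": window}
        catalog = VariantCatalog([VariantSite("chr1", 200, "A", "G"),
                                  VariantSite("chr1", 330, uniq[330],
                                              "A" if uniq[330] != "A" else "C")])
        aligner = ToyAligner(genome, max_mismatches=2)
        reads = [
            make_read("at_bias", "chr1", 170, genome_chr1[170:230]),
            make_read("at_unique", "chr1", 300, genome_chr1[300:360]),
        ]
        kept, metrics = run_bias_filter(reads, catalog, aligner, seed=0)
        names = {r.query_name for r in kept}
        assert names == {"at_unique"}
        assert metrics["reads_discarded_by_remap"] == 1

    def test_empty_catalog_passes_everything(self, make_read):
        catalog = VariantCatalog([])
        reads = [make_read(f"r{i}", "chr1", i * 40, "ACGT" * 10)
                 for i in range(5)]
        kept, metrics = run_bias_filter(reads, catalog, ToyExactAligner({}),
                                        seed=0)
        assert len(kept) == 5
        assert metrics["reads_intersecting"] == 0

    def test_paired_mates_discarded_together(self, make_read):
        catalog = VariantCatalog([VariantSite("chr1", 105, "A", "G")])
        genome = {"chr1": "C" * 2000}  # copies never remap concordantly
        r1 = make_read("frag", "chr1", 100, "A" * 30, flag=0x1 | 0x40)
        r2 = make_read("frag", "chr1", 400, "C" * 30, flag=0x1 | 0x80)
        kept, metrics = run_bias_filter([r1, r2], catalog,
                                        ToyExactAligner(genome), seed=0)
        assert kept == []  # clean mate discarded along with its pair
        assert metrics["mates_discarded_with_pair"] == 1
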