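"""Candidate-SNV catalog: gene models, feature regions, and variant filtering.

The catalog holds the heterozygous-candidate bi-allelic SNVs that every
downstream stage (bias filtering, allelic counting, gene-level testing)
operates on. Variants come from a VCF; regions come from a GFF3/GTF gene
annotation expanded to exons, introns, and 5 kb flanks. Only bi-allelic
single-nucleotide records overlapping those regions are retained — indels,
multi-allelic records and intergenic variants are dropped, with per-reason
tallies.

Coordinates: VCF and GFF are 1-based inclusive on disk; every in-memory
interval and position here is 0-based half-open. Conversion happens only in
the readers and writers.
"""

from __future__ import annotations

import bisect
import logging
import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

REGION_KINDS = ("exon", "intron", "flank5k")


@dataclass(frozen=True)
class VariantSite:
    """A bi-allelic SNV candidate. ``pos`` is 0-based; ``pos1`` the VCF view."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_id: str = ""

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position for {self.variant_id!r}")
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(f"non-SNV alleles {self.ref_allele}>{self.alt_allele}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not self.variant_id or self.variant_id == ".":
            object.__setattr__(self, "variant_id", f"{self.chrom}:{self.pos + 1}")

    @property
    def pos1(self) -> int:
        return self.pos + 1


@dataclass
class GeneModel:
    """A gene with merged, sorted exons; ``span`` covers all exons."""

    gene_id: str
    chrom: str
    span: tuple[int, int]
    exons: list[tuple[int, int]]

    def __post_init__(self):
        self.exons = merge_intervals(self.exons)
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        lo = min(self.span[0], self.exons[0][0])
        hi = max(self.span[1], self.exons[-1][1])
        self.span = (lo, hi)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
            if b_start > a_end
        ]


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent 0-based half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"degenerate interval ({s}, {e})")
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class RegionSet:
    """Genomic feature intervals (exon/intron/flank5k) with fast membership.

    Membership queries use a per-chromosome sorted, merged interval list
    built over all kinds together.
    """

    def __init__(self, intervals):
        self.intervals: list[tuple[str, int, int, str]] = []
        for chrom, start, end, kind in intervals:
            if end <= start:
                raise ValueError(f"degenerate interval {chrom}:{start}-{end}")
            if kind not in REGION_KINDS:
                raise ValueError(f"unknown region kind {kind!r}")
            self.intervals.append((chrom, int(start), int(end), kind))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        by_chrom = defaultdict(list)
        for chrom, start, end, _ in self.intervals:
            by_chrom[chrom].append((start, end))
        for chrom, ivs in by_chrom.items():
            merged = merge_intervals(ivs)
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    def __len__(self):
        return len(self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos) - 1
        return i >= 0 and pos < self._ends[chrom][i]

    def by_kind(self, kind: str) -> list[tuple[str, int, int]]:
        return [(c, s, e) for c, s, e, k in self.intervals if k == kind]


def build_feature_regions(genes, flank: int = 5000) -> RegionSet:
    """Expand gene models to exons, introns, and ``flank``-bp flanks.

    Flanks extend beyond the outermost exon boundaries of each gene and are
    truncated at position 0; intergenic space beyond the flanks is excluded.
    Genes without exons cannot be constructed (GeneModel enforces this), so
    every gene contributes at least one exon interval.
    """
    intervals = []
    for gene in genes:
        for s, e in gene.exons:
            intervals.append((gene.chrom, s, e, "exon"))
        for s, e in gene.introns():
            intervals.append((gene.chrom, s, e, "intron"))
        lo, hi = gene.exons[0][0], gene.exons[-1][1]
        if lo > 0:
            intervals.append((gene.chrom, max(0, lo - flank), lo, "flank5k"))
        intervals.append((gene.chrom, hi, hi + flank, "flank5k"))
    return RegionSet(intervals)


# --- annotation reading ----------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attr_field = attr_field.strip()
    if "=" in attr_field.split(";")[0]:  # GFF3 dialect: key=value
        pairs = {}
        for item in attr_field.split(";"):
            if "=" in item:
                k, _, v = item.partition("=")
                pairs[k.strip()] = v.strip()
        return pairs
    return dict(_GTF_ATTR.findall(attr_field))  # GTF dialect: key "value"


def _gene_id_of(attrs: dict[str, str], line_no: int) -> str:
    for key in ("gene_id", "Parent", "ID", "gene", "Name"):
        if key in attrs:
            # exon Parent may point at a transcript like "transcript:tx1";
            # strip any "type:" prefix
            return attrs[key].split(",")[0].split(":")[-1]
    raise ValueError(f"annotation line {line_no}: no gene identifier in attributes")


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from a GFF3 or GTF file (exon features grouped by gene).

    Malformed records raise with the offending line number; genes with zero
    exon features are skipped with a warning.
    """
    exons_by_gene: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    gene_order: list[tuple[str, str]] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise ValueError(f"annotation line {line_no}: expected 9 columns")
        chrom, _, feature, start, end, *_rest = fields[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ValueError(f"annotation line {line_no}: bad coordinates") from exc
        if end_i < start_i:
            raise ValueError(f"annotation line {line_no}: end < start")
        attrs = _parse_attributes(fields[8])
        if feature.lower() == "gene":
            key = (chrom, _gene_id_of(attrs, line_no))
            if key not in exons_by_gene:
                gene_order.append(key)
                exons_by_gene[key] = []
        elif feature.lower() == "exon":
            key = (chrom, _gene_id_of(attrs, line_no))
            if key not in exons_by_gene:
                gene_order.append(key)
            # GFF/GTF are 1-based inclusive
            exons_by_gene[key].append((start_i - 1, end_i))
    genes = []
    for chrom, gene_id in gene_order:
        exons = exons_by_gene[(chrom, gene_id)]
        if not exons:
            warnings.warn(f"gene {gene_id} has no exon features; skipped")
            continue
        merged = merge_intervals(exons)
        genes.append(
            GeneModel(gene_id=gene_id, chrom=chrom,
                      span=(merged[0][0], merged[-1][1]), exons=merged)
        )
    return genes


# --- the catalog -----------------------------------------------------------


class VariantCatalog:
    """Positionally indexed collection of candidate bi-allelic SNVs."""

    def __init__(self, sites):
        self.sites: list[VariantSite] = list(sites)
        self._index: dict[tuple[str, int], VariantSite] = {}
        for site in self.sites:
            key = (site.chrom, site.pos)
            if key in self._index:
                raise ValueError(f"duplicate catalog site at {site.chrom}:{site.pos1}")
            self._index[key] = site
        self._pos_by_chrom: dict[str, np.ndarray] = {}
        by_chrom = defaultdict(list)
        for site in self.sites:
            by_chrom[site.chrom].append(site.pos)
        for chrom, positions in by_chrom.items():
            self._pos_by_chrom[chrom] = np.asarray(sorted(positions), dtype=np.int64)
        self.gene_of: dict[tuple[str, int], list[str]] = {}

    def __len__(self):
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def get(self, chrom: str, pos: int) -> VariantSite | None:
        return self._index.get((chrom, pos))

    def sites_in(self, chrom: str, start: int, end: int) -> list[VariantSite]:
        """Catalog sites with start <= pos < end (0-based half-open)."""
        positions = self._pos_by_chrom.get(chrom)
        if positions is None:
            return []
        lo, hi = np.searchsorted(positions, [start, end])
        return [self._index[(chrom, int(p))] for p in positions[lo:hi]]

    # --- writers ---

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tid\tgene_id\n")
            for site in self.sites:
                genes = self.gene_of.get((site.chrom, site.pos), [])
                fh.write(
                    f"{site.chrom}\t{site.pos1}\t{site.ref_allele}\t"
                    f"{site.alt_allele}\t{site.variant_id}\t{','.join(genes) or '.'}\n"
                )

    def to_vcf(self, path) -> None:
        header = pysam.VariantHeader()
        chroms = sorted({s.chrom for s in self.sites})
        for chrom in chroms:
            max_pos = int(self._pos_by_chrom[chrom][-1]) + 1
            header.contigs.add(chrom, length=max_pos + 1_000_000)
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for site in sorted(self.sites, key=lambda s: (s.chrom, s.pos)):
                rec = out.new_record(
                    contig=site.chrom, start=site.pos, stop=site.pos + 1,
                    alleles=(site.ref_allele, site.alt_allele),
                    id=site.variant_id,
                )
                out.write(rec)


def load_variants(
    vcf_path,
    regions: RegionSet | None = None,
    chrom_aliases: dict[str, str] | None = None,
) -> tuple[VariantCatalog, Counter]:
    """Load bi-allelic SNVs from a VCF, restricted to ``regions``.

    Returns the catalog plus a tally of dropped records by reason
    (``multi_allelic``, ``indel``, ``outside_regions``, ``non_acgt``).
    Chromosome names are matched exactly; ``chrom_aliases`` maps VCF names
    onto annotation names (e.g. ``{"chr1": "1"}``) and is the only renaming
    applied.
    """
    aliases = chrom_aliases or {}
    dropped: Counter = Counter()
    sites = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            chrom = aliases.get(rec.chrom, rec.chrom)
            if rec.alts is None or len(rec.alts) != 1:
                dropped["multi_allelic"] += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                dropped["indel"] += 1
                continue
            if ref not in _BASES or alt not in _BASES:
                dropped["non_acgt"] += 1
                continue
            if regions is not None and not regions.contains(chrom, rec.start):
                dropped["outside_regions"] += 1
                continue
            sites.append(
                VariantSite(chrom=chrom, pos=rec.start, ref_allele=ref,
                            alt_allele=alt, variant_id=rec.id or "")
            )
    if not sites:
        warnings.warn("no variants fell inside the feature regions")
    logger.info("catalog: %d sites kept, dropped %s", len(sites), dict(dropped))
    return VariantCatalog(sites), dropped


def map_sites_to_genes(
    catalog: VariantCatalog,
    genes,
    flank: int = 5000,
    exon_only: bool = False,
) -> dict[tuple[str, int], list[str]]:
    """Assign every catalog site to each gene whose footprint contains it.

    A gene's footprint is its exon-bounded span extended by ``flank`` bases
    (or its exons only when ``exon_only``). Sites inside two overlapping
    genes receive both assignments; unassignable sites map to an empty list
    and remain available for SNV-level analyses.
    """
    assignment: dict[tuple[str, int], list[str]] = {
        (s.chrom, s.pos): [] for s in catalog
    }
    for gene in genes:
        if exon_only:
            windows = gene.exons
        else:
            lo, hi = gene.exons[0][0], gene.exons[-1][1]
            windows = [(max(0, lo - flank), hi + flank)]
        for start, end in windows:
            for site in catalog.sites_in(gene.chrom, start, end):
                assignment[(site.chrom, site.pos)].append(gene.gene_id)
    catalog.gene_of = assignment
    return assignment
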