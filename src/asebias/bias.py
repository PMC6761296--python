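"""Reference-mapping-bias removal by allele-flipped read remapping.

Reads overlapping catalog SNVs get synthetic copies with every combination
of ref/alt alleles at the overlapped sites (2^n combinations for n sites,
capped at n = 6, i.e. 64). The copies are pushed through an aligner; if any
copy fails to map uniquely back to the original coordinate, the original
read is discarded. Reads carrying the reference allele at a site whose
alternate haplotype is ambiguous in the genome are thereby removed along
with their alt counterparts, instead of surviving and inflating the
reference ratio. Afterwards positional duplicates are removed by an
unbiased (seeded-random, not quality-based) choice.
"""

from __future__ import annotations

import itertools
import subprocess
import tempfile
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .catalog import VariantCatalog, VariantSite

MAX_SITES_DEFAULT = 6

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RemapResult:
    """Outcome of remapping one synthetic copy."""

    mapped: bool
    unique: bool = False
    chrom: str | None = None
    pos: int | None = None  # 0-based leftmost
    query_span: int | None = None


@dataclass
class SyntheticReadSet:
    """A read overlapping catalog sites plus its allele-flipped copies."""

    read: pysam.AlignedSegment
    sites: list[tuple[VariantSite, int]]  # (site, query offset)
    copies: list[tuple[str, str]] = field(default_factory=list)  # (copy name, seq)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def overlapped_sites(
    read: pysam.AlignedSegment, catalog: VariantCatalog
) -> list[tuple[VariantSite, int]]:
    """Catalog sites overlapped by the read at aligned (M/X/=) positions.

    Offsets follow the CIGAR: insertions, deletions and clips shift them,
    and sites falling inside deletions or clipped segments are not counted.
    """
    if read.is_unmapped:
        return []
    hits = catalog.sites_in(read.reference_name, read.reference_start, read.reference_end)
    if not hits:
        return []
    wanted = {site.pos: site for site in hits}
    out = []
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        site = wanted.get(rpos)
        if site is not None:
            out.append((site, qpos))
    return out


def make_synthetic_reads(
    read: pysam.AlignedSegment,
    sites: list[tuple[VariantSite, int]],
    max_sites: int = MAX_SITES_DEFAULT,
    metrics: Counter | None = None,
) -> SyntheticReadSet | None:
    """Enumerate allele-flipped copies of a read over its overlapped sites.

    All 2^n ref/alt combinations are generated; the original combination is
    counted among them but not re-emitted, so 2^n - 1 new sequences are
    returned. A read overlapping more than ``max_sites`` sites is discarded
    entirely (returns None). A site where the read base matches neither
    allele is skipped for flipping; both events are tallied in ``metrics``.
    """
    metrics = metrics if metrics is not None else Counter()
    if len(sites) > max_sites:
        metrics["reads_discarded_too_many_sites"] += 1
        return None
    seq = read.query_sequence
    flippable = []
    for site, offset in sites:
        base = seq[offset]
        if base == site.ref_allele:
            flippable.append((offset, site.ref_allele, site.alt_allele))
        elif base == site.alt_allele:
            flippable.append((offset, site.alt_allele, site.ref_allele))
        else:
            metrics["sites_skipped_neither_allele"] += 1
    sset = SyntheticReadSet(read=read, sites=sites)
    chars = list(seq)
    for i, combo in enumerate(itertools.product((0, 1), repeat=len(flippable))):
        if not any(combo):
            continue  # the original combination
        copy = chars[:]
        for flag, (offset, own, other) in zip(combo, flippable):
            if flag:
                copy[offset] = other
        sset.copies.append((f"{read.query_name}|flip{i}", "".join(copy)))
    return sset


def filter_by_remap(
    sset: SyntheticReadSet, remapped: dict[str, RemapResult]
) -> bool:
    """Keep the original read iff every flipped copy remapped concordantly.

    Concordant means: mapped, uniquely, to the read's original
    (chrom, pos) with the same query span. Any unmapped, multi-mapped or
    displaced copy discards the read. A copy with no remap result is a
    pipeline-integrity error.
    """
    read = sset.read
    span = read.infer_query_length()
    for name, _ in sset.copies:
        if name not in remapped:
            raise RuntimeError(f"missing remap result for synthetic copy {name}")
        res = remapped[name]
        if not (res.mapped and res.unique):
            return False
        if res.chrom != read.reference_name or res.pos != read.reference_start:
            return False
        if res.query_span is not None and span is not None and res.query_span != span:
            return False
    return True


# ---------------------------------------------------------------------------
# Aligner contract
# ---------------------------------------------------------------------------


class ToyAligner:
    """Best-match aligner over a small in-memory genome.

    Seed-and-verify: the query is split into ``max_mismatches + 1`` chunks
    (by pigeonhole, at least one chunk matches exactly wherever the full
    query aligns with at most that many substitutions); exact chunk hits
    nominate candidate positions on both strands, which are verified by
    substitution count. The uniquely best-scoring position wins; ties are
    multi-mapped; no candidate within the mismatch budget is unmapped.
    Deterministic by construction. With ``max_mismatches=0`` this is plain
    exact-substring matching. Intended for desk-scale toy genomes
    (<= a few hundred kb); no indels or splicing.
    """

    def __init__(self, genome: dict[str, str], max_mismatches: int = 0):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.max_mismatches = int(max_mismatches)
        self._arr = {c: np.frombuffer(s.encode(), dtype=np.uint8)
                     for c, s in self.genome.items()}

    def _hits(self, seq: str) -> list[tuple[int, str, int, str]]:
        """All (mismatches, chrom, pos, strand) within the budget."""
        hits = {}
        for probe, strand in ((seq, "+"), (revcomp(seq), "-")):
            arr = np.frombuffer(probe.encode(), dtype=np.uint8)
            k = len(probe)
            bounds = np.linspace(0, k, self.max_mismatches + 2).astype(int)
            candidates = set()
            for lo, hi in zip(bounds, bounds[1:]):
                chunk = probe[lo:hi]
                if not chunk:
                    continue
                for chrom, ref in self.genome.items():
                    start = ref.find(chunk)
                    while start != -1:
                        cand = start - lo
                        if 0 <= cand <= len(ref) - k:
                            candidates.add((chrom, cand))
                        start = ref.find(chunk, start + 1)
            for chrom, cand in candidates:
                mm = int((self._arr[chrom][cand:cand + k] != arr).sum())
                if mm <= self.max_mismatches:
                    key = (chrom, cand)
                    if key not in hits or mm < hits[key][0]:
                        hits[key] = (mm, chrom, cand, strand)
        return sorted(hits.values())

    def align_one(self, seq: str, best_hit_on_tie: bool = False) -> RemapResult:
        hits = self._hits(seq.upper())
        if not hits:
            return RemapResult(mapped=False)
        best_mm = hits[0][0]
        best = [h for h in hits if h[0] == best_mm]
        if len(best) == 1:
            _, chrom, pos, _ = best[0]
            return RemapResult(mapped=True, unique=True, chrom=chrom, pos=pos,
                               query_span=len(seq))
        if best_hit_on_tie:
            _, chrom, pos, _ = best[0]
            return RemapResult(mapped=True, unique=False, chrom=chrom, pos=pos,
                               query_span=len(seq))
        return RemapResult(mapped=True, unique=False)

    def __call__(
        self, sequences: list[tuple[str, str]], best_hit_on_tie: bool = False
    ) -> dict[str, RemapResult]:
        return {name: self.align_one(seq, best_hit_on_tie)
                for name, seq in sequences}


class ToyExactAligner(ToyAligner):
    """Exact-substring special case of :class:`ToyAligner`."""

    def __init__(self, genome: dict[str, str]):
        super().__init__(genome, max_mismatches=0)


class ExternalAligner:
    """Shim around an external aligner command (e.g. a HISAT2 invocation).

    Writes the synthetic copies as FASTQ, runs ``command`` with ``{fastq}``
    and ``{sam}`` placeholders substituted, and reads the resulting SAM.
    MAPQ 0 or the secondary/supplementary flags are treated as
    non-unique. The command, including any mismatch-penalty settings, is
    configuration rather than code.
    """

    def __init__(self, command: str, workdir=None):
        self.command = command
        self.workdir = workdir

    def __call__(self, sequences: list[tuple[str, str]]) -> dict[str, RemapResult]:
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            fastq = Path(tmp) / "copies.fastq"
            sam = Path(tmp) / "copies.sam"
            with open(fastq, "w") as fh:
                for name, seq in sequences:
                    fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            cmd = self.command.format(fastq=fastq, sam=sam)
            subprocess.run(cmd, shell=True, check=True)
            out = {name: RemapResult(mapped=False) for name, _ in sequences}
            seen_twice = set()
            with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
                for rec in fh:
                    if rec.is_unmapped:
                        continue
                    if rec.is_secondary or rec.is_supplementary or rec.mapping_quality == 0:
                        seen_twice.add(rec.query_name)
                        continue
                    out[rec.query_name] = RemapResult(
                        mapped=True, unique=True, chrom=rec.reference_name,
                        pos=rec.reference_start, query_span=rec.infer_query_length(),
                    )
            for name in seen_twice:
                res = out[name]
                out[name] = RemapResult(mapped=res.mapped, unique=False)
            return out


# ---------------------------------------------------------------------------
# Duplicate removal and pipeline driver
# ---------------------------------------------------------------------------


def dedup_unbiased(
    reads: list[pysam.AlignedSegment], seed: int, metrics: Counter | None = None
) -> list[pysam.AlignedSegment]:
    """Remove positional duplicates, keeping one per group uniformly at random.

    Duplicates share (chrom, pos, strand, CIGAR). Choosing the survivor at
    random rather than by quality keeps allele retention unbiased. Input
    order is preserved for the survivors; reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    groups: dict[tuple, list[int]] = defaultdict(list)
    for i, read in enumerate(reads):
        key = (read.reference_name, read.reference_start,
               read.is_reverse, read.cigarstring)
        groups[key].append(i)
    keep = set()
    for key in sorted(groups, key=repr):
        members = groups[key]
        keep.add(members[int(rng.integers(len(members)))])
    if metrics is not None:
        metrics["duplicates_removed"] += len(reads) - len(keep)
    return [r for i, r in enumerate(reads) if i in keep]


def run_bias_filter(
    reads: list[pysam.AlignedSegment],
    catalog: VariantCatalog,
    aligner,
    seed: int,
    max_sites: int = MAX_SITES_DEFAULT,
    dedup: bool = True,
) -> tuple[list[pysam.AlignedSegment], Counter]:
    """Full bias-removal pass over an alignment stream.

    Splits reads into clean (no catalog-site overlap) and intersecting,
    builds flipped copies, remaps them through ``aligner``, keeps only
    concordant reads, merges, and optionally deduplicates. Paired-end mates
    are treated as a unit: if either mate is discarded, both are. Returns
    the retained reads and a metrics counter.
    """
    metrics: Counter = Counter()
    metrics["reads_in"] = len(reads)
    ssets: list[SyntheticReadSet] = []
    verdict_clean: list[pysam.AlignedSegment] = []
    discarded_names: set[str] = set()
    for read in reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        sites = overlapped_sites(read, catalog)
        if not sites:
            verdict_clean.append(read)
            continue
        metrics["reads_intersecting"] += 1
        sset = make_synthetic_reads(read, sites, max_sites=max_sites, metrics=metrics)
        if sset is None:
            discarded_names.add(read.query_name)
            continue
        ssets.append(sset)

    all_copies = [copy for sset in ssets for copy in sset.copies]
    metrics["synthetic_copies"] = len(all_copies)
    remapped = aligner(all_copies) if all_copies else {}

    kept_intersecting: list[pysam.AlignedSegment] = []
    for sset in ssets:
        if filter_by_remap(sset, remapped):
            kept_intersecting.append(sset.read)
        else:
            metrics["reads_discarded_by_remap"] += 1
            discarded_names.add(sset.read.query_name)

    merged = []
    for read in verdict_clean + kept_intersecting:
        if read.is_paired and read.query_name in discarded_names:
            metrics["mates_discarded_with_pair"] += 1
            continue
        merged.append(read)
    merged.sort(key=lambda r: (r.reference_name, r.reference_start))

    if dedup:
        merged = dedup_unbiased(merged, seed=seed, metrics=metrics)
    metrics["reads_out"] = len(merged)
    return merged, metrics
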