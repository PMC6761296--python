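"""Quality-gated allelic read counting and bi-allelic depth filtration.

Counting follows ASEReadCounter semantics: at each catalog site, reads with
mapping quality >= 50 contribute the base aligned over the site when that
base's quality is >= 25; duplicates and secondary/supplementary alignments
are excluded, and overlapping mates of a proper pair contribute once per
site (fragment-level counting). Bases matching neither catalogued allele
are tallied separately and never enter the ref/alt ratio denominator.

Filtration then enforces the bi-allelic depth rule: total >= 10 reads, each
allele >= 3 reads and >= 1% of the site total. Sites with observed
mono-allelic expression are thereby removed without any allelic-ratio
cutoff.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .catalog import VariantCatalog

ASE_COLUMNS = [
    "contig", "position", "variantID", "refAllele", "altAllele",
    "refCount", "altCount", "totalCount", "otherBases", "sample",
]

MIN_MAPQ_DEFAULT = 50
MIN_BASEQ_DEFAULT = 25
MIN_TOTAL_DEFAULT = 10
MIN_ALLELE_DEFAULT = 3
MIN_FRAC_DEFAULT = 0.01


@dataclass
class CountTable:
    """Per-site ref/alt counts with the parameters that produced them.

    ``df`` uses ASEReadCounter column conventions (``position`` is 1-based);
    ``provenance`` records quality gates and filter parameters;
    ``drop_reasons`` is populated by :func:`filter_biallelic`.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    drop_reasons: Counter = field(default_factory=Counter)

    def __len__(self):
        return len(self.df)

    @property
    def ref_ratio(self) -> np.ndarray:
        total = self.df["totalCount"].to_numpy(dtype=float)
        ref = self.df["refCount"].to_numpy(dtype=float)
        ratio = np.full(total.shape, np.nan)
        np.divide(ref, total, out=ratio, where=total > 0)
        return ratio

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"contig": str})
        missing = [c for c in ASE_COLUMNS[:-1] if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        if "sample" not in df.columns:
            df["sample"] = "sample"
        return cls(df=df)


def count_alleles(
    reads,
    catalog: VariantCatalog,
    sample_id: str = "sample",
    min_mapq: int = MIN_MAPQ_DEFAULT,
    min_baseq: int = MIN_BASEQ_DEFAULT,
) -> CountTable:
    """Tally ref/alt/other bases over every catalog site.

    ``reads`` is an iterable of aligned segments (already bias-filtered).
    Fragment-level counting: when both mates of a pair cover a site with the
    same base, the fragment contributes once; mates disagreeing at the site
    contribute nothing there. Sites on chromosomes absent from the
    alignments get zero-count records.
    """
    # site -> fragment name -> (base, baseq); None marks a discordant pair
    per_site: dict[tuple[str, int], dict[str, tuple[str, int] | None]] = {
        (s.chrom, s.pos): {} for s in catalog
    }
    for read in reads:
        if (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.is_duplicate):
            continue
        if read.mapping_quality < min_mapq:
            continue
        hits = catalog.sites_in(
            read.reference_name, read.reference_start, read.reference_end
        )
        if not hits:
            continue
        wanted = {s.pos for s in hits}
        seq = read.query_sequence
        quals = read.query_qualities
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            if rpos not in wanted:
                continue
            base, bq = seq[qpos], quals[qpos]
            if bq < min_baseq:
                continue
            frags = per_site[(read.reference_name, rpos)]
            name = read.query_name
            if name in frags:
                prev = frags[name]
                if prev is not None and prev[0] != base:
                    frags[name] = None  # overlapping mates disagree
            else:
                frags[name] = (base, bq)

    rows = []
    for site in catalog:
        tallies = Counter(
            v[0] for v in per_site[(site.chrom, site.pos)].values() if v is not None
        )
        ref_n = tallies.get(site.ref_allele, 0)
        alt_n = tallies.get(site.alt_allele, 0)
        other = sum(tallies.values()) - ref_n - alt_n
        rows.append((site.chrom, site.pos1, site.variant_id, site.ref_allele,
                     site.alt_allele, ref_n, alt_n, ref_n + alt_n, other, sample_id))
    df = pd.DataFrame(rows, columns=ASE_COLUMNS)
    return CountTable(
        df=df, provenance={"min_mapq": min_mapq, "min_baseq": min_baseq,
                           "sample_id": sample_id},
    )


def filter_biallelic(
    table: CountTable,
    min_total: int = MIN_TOTAL_DEFAULT,
    min_allele: int = MIN_ALLELE_DEFAULT,
    min_frac: float = MIN_FRAC_DEFAULT,
) -> CountTable:
    """Apply the bi-allelic depth filtration rule.

    A site survives iff total >= ``min_total``, both allele counts are
    >= ``min_allele``, and both allele fractions of the site total are
    >= ``min_frac``. Drop reasons are tallied on the returned table. The
    operation is idempotent. Note the fraction rule only binds beyond
    total = min_allele/min_frac (300 at the defaults).
    """
    df = table.df
    total = df["totalCount"].to_numpy(dtype=float)
    ref = df["refCount"].to_numpy(dtype=float)
    alt = df["altCount"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_ok = (ref / total >= min_frac) & (alt / total >= min_frac)
    keep_total = total >= min_total
    keep_allele = (ref >= min_allele) & (alt >= min_allele)
    keep = keep_total & keep_allele & frac_ok
    reasons = Counter(
        low_total=int((~keep_total).sum()),
        low_allele_count=int((keep_total & ~keep_allele).sum()),
        low_allele_fraction=int((keep_total & keep_allele & ~frac_ok).sum()),
    )
    out = CountTable(
        df=df[keep].reset_index(drop=True),
        provenance={**table.provenance, "min_total": min_total,
                    "min_allele": min_allele, "min_frac": min_frac},
        drop_reasons=reasons,
    )
    return out


def ref_ratio_summary(
    table: CountTable, lo: float = 0.49, hi: float = 0.51, n_bins: int = 50
) -> dict:
    """Global reference-ratio QC: histogram, balance bins, and 0/1 inflation.

    Bins the per-site ref ratio, counts sites below ``lo``, within
    [``lo``, ``hi``] (balanced), and above ``hi``, and flags any mass at
    exactly 0 or 1 — which is impossible after bi-allelic filtration and
    would indicate a filter integrity problem.
    """
    ratios = table.ref_ratio
    ratios = ratios[~np.isnan(ratios)]
    if ratios.size == 0:
        return {"n_sites": 0, "histogram": None, "below": 0, "balanced": 0,
                "above": 0, "mean": np.nan, "median": np.nan,
                "n_ratio_zero_or_one": 0}
    hist, edges = np.histogram(ratios, bins=n_bins, range=(0.0, 1.0))
    return {
        "n_sites": int(ratios.size),
        "histogram": (hist, edges),
        "below": int((ratios < lo).sum()),
        "balanced": int(((ratios >= lo) & (ratios <= hi)).sum()),
        "above": int((ratios > hi).sum()),
        "mean": float(ratios.mean()),
        "median": float(np.median(ratios)),
        "n_ratio_zero_or_one": int(((ratios == 0.0) | (ratios == 1.0)).sum()),
    }
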