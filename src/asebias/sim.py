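"""Synthetic data: toy diploid genomes, reads, and allelic count tables.

Every pipeline stage is testable without downloads. Two generators:

* :func:`simulate_counts` — per-site ref/alt count tables (optionally
  paired conditions and multiple individuals) drawn from Binomial or
  Beta-Binomial allele sampling, with ground-truth labels for every gene
  and site.
* :func:`simulate_reads` — a toy genome with gene models, a catalog of
  heterozygous exonic SNVs, and reads sampled from two haplotypes that
  differ exactly at those SNVs. Configurable "bias" sites plant a decoy
  copy of the alternate haplotype elsewhere in the genome, so alt-carrying
  reads align there perfectly and desert the gene locus — reproducing
  reference mapping bias under any mismatch-scoring aligner.

One global seed expands into independent per-component child streams via
``numpy``'s SeedSequence (seeded as ``(seed, stream_tag)``), so stages can
be re-run independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .bias import ToyAligner
from .catalog import GeneModel, VariantCatalog, VariantSite
from .counting import ASE_COLUMNS, CountTable

_B = np.array(list("ACGT"))

# stream tags for child-seed derivation
_STREAM_GENOME = 1
_STREAM_COUNTS = 2
_STREAM_READS = 3


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic genome / reads / counts.

    Depths emulate deep bulk RNA-seq at desk scale (mean ~100x at
    heterozygous sites); the baseline allelic ratio is 0.5 and effect genes
    shift it to ``effect_p``. Condition effects give the listed genes a
    ratio of ``condition_p[0]`` in condition A and ``condition_p[1]`` in B.
    """

    seed: int
    n_genes: int = 30
    snvs_per_gene: int = 5
    depth_mean: float = 100.0        # Poisson mean; None-like via depth_fixed
    depth_fixed: int | None = None   # overrides depth_mean when set
    baseline_p: float = 0.5
    n_effect_genes: int = 0
    effect_p: float = 0.7
    n_condition_genes: int = 0
    condition_p: tuple = (0.5, 0.9)
    # in condition genes, how many SNVs actually shift (None = all of them);
    # the rest stay at baseline — a strong site diluted inside a null gene
    n_condition_snvs: int | None = None
    rho: float = 0.0                 # beta-binomial intra-class correlation
    n_individuals: int = 1
    sexes: tuple = ()
    # read simulation
    read_length: int = 125
    gene_length: int = 600
    gene_spacing: int = 1200
    reads_per_gene: int = 400
    n_bias_sites: int = 0
    chrom: str = "chr1"

    def __post_init__(self):
        for p in (self.baseline_p, self.effect_p, *self.condition_p):
            if not 0.0 < p < 1.0:
                raise ValueError("allele probabilities must lie in (0, 1)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.depth_fixed is not None and self.depth_fixed < 1:
            raise ValueError("depths must be >= 1")
        if self.n_effect_genes + self.n_condition_genes > self.n_genes:
            raise ValueError("more effect/condition genes than genes")
        if self.read_length > self.gene_length:
            raise ValueError("read length exceeds gene length")
        if self.sexes and len(self.sexes) != self.n_individuals:
            raise ValueError("one sex label per individual required")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _rng(config: SimConfig, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng((config.seed, stream, extra))


def _site_layout(config: SimConfig) -> pd.DataFrame:
    """Deterministic gene/SNV layout plus per-site true allele probabilities."""
    rows = []
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:04d}"
        gene_start = config.gene_spacing + g * (config.gene_length + config.gene_spacing)
        if g < config.n_effect_genes:
            role, p_a, p_b = "effect", config.effect_p, config.effect_p
        elif g < config.n_effect_genes + config.n_condition_genes:
            role, (p_a, p_b) = "condition", config.condition_p
        else:
            role, p_a, p_b = "null", config.baseline_p, config.baseline_p
        offsets = np.linspace(
            config.read_length // 2,
            config.gene_length - config.read_length // 2 - 1,
            config.snvs_per_gene,
        ).astype(int)
        for j, off in enumerate(offsets):
            site_pa, site_pb = p_a, p_b
            if (role == "condition" and config.n_condition_snvs is not None
                    and j >= config.n_condition_snvs):
                site_pa = site_pb = config.baseline_p
            rows.append((gene_id, config.chrom, gene_start, int(gene_start + off),
                         role, site_pa, site_pb, False))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "gene_start", "pos",
                                     "role", "p_a", "p_b", "bias_site"])
    if config.n_bias_sites:
        null_genes = df[df.role == "null"]["gene_id"].unique()
        if len(null_genes) < config.n_bias_sites:
            raise ValueError("not enough null genes to host bias sites")
        for gene_id in null_genes[: config.n_bias_sites]:
            idx = df.index[df.gene_id == gene_id]
            df.loc[idx[len(idx) // 2], "bias_site"] = True
    return df


def _draw_ref_counts(rng, depths, p, rho):
    if rho > 0:
        a = p * (1 - rho) / rho
        b = (1 - p) * (1 - rho) / rho
        p = rng.beta(a, b, size=depths.shape)
    return rng.binomial(depths, p)


@dataclass
class SimulatedCounts:
    """Count tables plus ground truth from :func:`simulate_counts`."""

    tables: dict[str, CountTable]                      # individual -> table (cond A)
    paired: dict[str, tuple[CountTable, CountTable]]   # individual -> (A, B)
    gene_of: dict[tuple[str, int], list[str]]
    truth: pd.DataFrame
    config: SimConfig


def simulate_counts(config: SimConfig) -> SimulatedCounts:
    """Draw per-site allelic count tables for every individual.

    All SNVs of a gene share its true allelic ratio (a cis effect).
    Condition-B tables are produced only when ``n_condition_genes`` > 0 or
    explicitly useful; they are always generated so paired analyses can run
    (null genes are balanced in both conditions).
    """
    layout = _site_layout(config)
    depths_rng = _rng(config, _STREAM_COUNTS, 0)
    individuals = [f"ind{i + 1}" for i in range(config.n_individuals)]
    tables: dict[str, CountTable] = {}
    paired: dict[str, tuple[CountTable, CountTable]] = {}
    n_sites = len(layout)
    for i, ind in enumerate(individuals):
        rng = _rng(config, _STREAM_COUNTS, i + 1)
        if config.depth_fixed is not None:
            depth_a = np.full(n_sites, config.depth_fixed, dtype=np.int64)
            depth_b = depth_a.copy()
        else:
            depth_a = 1 + rng.poisson(config.depth_mean - 1, n_sites)
            depth_b = 1 + rng.poisson(config.depth_mean - 1, n_sites)
        ref_a = _draw_ref_counts(rng, depth_a, layout["p_a"].to_numpy(), config.rho)
        ref_b = _draw_ref_counts(rng, depth_b, layout["p_b"].to_numpy(), config.rho)

        def _table(ref, depth):
            df = pd.DataFrame({
                "contig": layout["chrom"],
                "position": layout["pos"] + 1,
                "variantID": [f"{c}:{p + 1}" for c, p in
                              zip(layout["chrom"], layout["pos"])],
                "refAllele": "A", "altAllele": "G",
                "refCount": ref, "altCount": depth - ref,
                "totalCount": depth, "otherBases": 0, "sample": ind,
            })
            return CountTable(df=df[ASE_COLUMNS],
                              provenance={"simulated": True, "sample_id": ind})

        tables[ind] = _table(ref_a, depth_a)
        paired[ind] = (tables[ind], _table(ref_b, depth_b))
    gene_of = {(c, int(p)): [g] for c, p, g in
               zip(layout["chrom"], layout["pos"], layout["gene_id"])}
    _ = depths_rng  # reserved stream
    return SimulatedCounts(tables=tables, paired=paired, gene_of=gene_of,
                           truth=layout, config=config)


# ---------------------------------------------------------------------------
# Read-level simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedReads:
    """Toy genome, aligned reads, catalog and truth from :func:`simulate_reads`."""

    genome: dict[str, str]
    reads: list                       # pysam.AlignedSegment, coordinate-sorted
    header: pysam.AlignmentHeader
    catalog: VariantCatalog
    genes: list[GeneModel]
    gene_of: dict[tuple[str, int], list[str]]
    truth: pd.DataFrame
    config: SimConfig

    def aligner(self, max_mismatches: int | None = None) -> ToyAligner:
        mm = self.config.snvs_per_gene if max_mismatches is None else max_mismatches
        return ToyAligner(self.genome, max_mismatches=mm)

    def write(self, out_dir) -> dict[str, Path]:
        """Write FASTA / SAM / VCF / GFF3 / truth TSV / config JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["fasta"] = out / "genome.fa"
        with open(paths["fasta"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        paths["sam"] = out / "reads.sam"
        with pysam.AlignmentFile(str(paths["sam"]), "wh", header=self.header) as fh:
            for read in self.reads:
                fh.write(read)
        paths["vcf"] = out / "variants.vcf"
        self.catalog.to_vcf(paths["vcf"])
        paths["gff"] = out / "genes.gff3"
        with open(paths["gff"], "w") as fh:
            fh.write("##gff-version 3\n")
            for gene in self.genes:
                s, e = gene.span
                fh.write(f"{gene.chrom}\ttoy\tgene\t{s + 1}\t{e}\t.\t+\t."
                         f"\tID=gene:{gene.gene_id}\n")
                for xs, xe in gene.exons:
                    fh.write(f"{gene.chrom}\ttoy\texon\t{xs + 1}\t{xe}\t.\t+\t."
                             f"\tParent=gene:{gene.gene_id}\n")
        paths["truth"] = out / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["config"] = out / "sim_config.json"
        paths["config"].write_text(self.config.to_json())
        return paths


def simulate_reads(config: SimConfig) -> SimulatedReads:
    """Generate a toy genome, haplotype-consistent reads, and their alignments.

    The reference genome carries the ref allele at every catalog SNV; each
    gene has a ref and an alt haplotype differing exactly at its SNVs, and
    each read is drawn whole from one haplotype (probability of the ref
    haplotype = the gene's true ratio). Reads are aligned with the built-in
    mismatch-tolerant exact-scoring aligner: a uniquely best-matching
    position gets MAPQ 60, ties get MAPQ 0 at the first best hit. At
    configured bias sites a decoy contig carries the alternate-haplotype
    window around the site, so alt reads covering it align perfectly to the
    decoy instead of the gene.
    """
    genome_len_needed = (config.gene_spacing
                         + config.n_genes * (config.gene_length + config.gene_spacing))
    if genome_len_needed > 400_000:
        raise ValueError("toy genome would exceed desk scale; shrink the config")
    layout = _site_layout(config)
    grng = _rng(config, _STREAM_GENOME)
    chrom_seq = grng.choice(_B, size=genome_len_needed)

    sites = []
    for _, row in layout.iterrows():
        ref_base = str(chrom_seq[row.pos])
        alt_base = str(grng.choice([b for b in "ACGT" if b != ref_base]))
        sites.append(VariantSite(chrom=row.chrom, pos=int(row.pos),
                                 ref_allele=ref_base, alt_allele=alt_base))
    catalog = VariantCatalog(sites)
    site_by_pos = {s.pos: s for s in sites}

    genes = []
    for gene_id, grp in layout.groupby("gene_id", sort=True):
        start = int(grp["gene_start"].iloc[0])
        genes.append(GeneModel(gene_id=gene_id, chrom=config.chrom,
                               span=(start, start + config.gene_length),
                               exons=[(start, start + config.gene_length)]))

    genome = {config.chrom: "".join(chrom_seq)}
    # decoy contigs: alternate-haplotype windows around each bias site
    rl = config.read_length
    for n_decoy, (_, row) in enumerate(layout[layout.bias_site].iterrows()):
        lo = row.pos - (rl - 1)
        hi = row.pos + rl
        window = list(chrom_seq[lo:hi])
        for pos in range(lo, hi):
            if pos in site_by_pos:
                window[pos - lo] = site_by_pos[pos].alt_allele
        genome[f"decoy{n_decoy + 1}"] = "".join(window)

    # haplotype-consistent reads, then alignment
    rrng = _rng(config, _STREAM_READS)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()],
    })
    raw_reads = []
    for gene, (gene_id, grp) in zip(genes, layout.groupby("gene_id", sort=True)):
        start, end = gene.span
        hap_ref = genome[config.chrom][start:end]
        hap_alt = list(hap_ref)
        for pos in grp["pos"]:
            hap_alt[pos - start] = site_by_pos[pos].alt_allele
        hap_alt = "".join(hap_alt)
        p_ref = float(grp["p_a"].iloc[0])
        starts = rrng.integers(0, config.gene_length - rl + 1,
                               size=config.reads_per_gene)
        is_ref = rrng.random(config.reads_per_gene) < p_ref
        for i, (s0, ref_hap) in enumerate(zip(starts, is_ref)):
            hap = hap_ref if ref_hap else hap_alt
            raw_reads.append((f"{gene_id}:r{i}", int(start + s0),
                              hap[s0:s0 + rl], bool(ref_hap)))

    aligner = ToyAligner(genome, max_mismatches=config.snvs_per_gene)
    results = aligner([(name, seq) for name, _, seq, _ in raw_reads],
                      best_hit_on_tie=True)
    reads = []
    for name, true_pos, seq, _ in raw_reads:
        res = results[name]
        if not res.mapped:
            continue
        seg = pysam.AlignedSegment(header)
        seg.query_name = name
        seg.query_sequence = seq
        seg.reference_name = res.chrom
        seg.reference_start = res.pos
        seg.mapping_quality = 60 if res.unique else 0
        seg.cigarstring = f"{rl}M"
        seg.query_qualities = pysam.qualitystring_to_array("I" * rl)
        seg.flag = 0
        reads.append(seg)
    reads.sort(key=lambda r: (r.reference_name, r.reference_start))

    gene_of = {(config.chrom, int(p)): [g]
               for p, g in zip(layout["pos"], layout["gene_id"])}
    return SimulatedReads(genome=genome, reads=reads, header=header,
                          catalog=catalog, genes=genes, gene_of=gene_of,
                          truth=layout, config=config)
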