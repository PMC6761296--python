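# Methods

`asebias` measures allele-specific expression (ASE) from RNA-seq: at a
heterozygous bi-allelic SNV the two alleles of one individual are sequenced
together, and the reference-allele ratio `ref / (ref + alt)` estimates the
relative expression of the two haplotypes. Departure from 0.5 (allelic
imbalance) indicates cis-acting regulatory variation. This note records the
models, the parameter choices, and the limits of what the synthetic-data
tests demonstrate.

## Reference-mapping-bias removal

Reads are mapped against a single-haplotype reference, so a read carrying
the alternate allele pays a mismatch penalty the reference read does not.
Around paralogous or repetitive sequence this loses alt reads
preferentially and inflates the reference ratio, producing false ASE. The
removal strategy is flip-and-remap: every read overlapping catalog SNVs at
aligned (CIGAR match) positions gets synthetic copies enumerating all
ref/alt combinations at those sites — `2^n` combinations for `n` sites,
the original included in the count but not re-emitted. All copies are
pushed through an aligner, and the read survives only if every copy maps
uniquely back to the original coordinate with the same query span. Reads
overlapping more than `max_sites = 6` SNVs (i.e. more than 64
combinations) are discarded outright and tallied in the metrics.

Flips are strictly bi-allelic (ref <-> alt); a read base matching neither
allele leaves that site unflipped, with a tally. Paired mates are a unit:
discarding either discards both, so no orphan half-fragments bias the
counts. Positional duplicates — same (chrom, pos, strand, CIGAR) — are then
reduced to one read chosen uniformly at random under the pipeline seed;
choosing by base quality would favour whichever allele sequenced better.

The aligner is a contract, not a dependency: anything that maps (name,
sequence) pairs and reports unmapped and multi-mapped reads explicitly.
Production use wraps an external spliced aligner command (FASTQ out, SAM
in); tests and simulations use the built-in `ToyAligner`, a seed-and-verify
substitution matcher over an in-memory genome. It splits the query into
`max_mismatches + 1` chunks (pigeonhole: one chunk is exact wherever the
full query fits the budget), nominates candidate positions from exact chunk
hits on both strands, verifies by Hamming distance, and calls the uniquely
best position mapped, ties multi-mapped. It handles no indels or splicing —
sufficient for the ungapped toy reads the simulator produces.

Remap concordance is exact (chrom, pos) equality with no slack window: the
strictest reading of "maps elsewhere", and the right one for a
substitution-only toy aligner whose coordinates are deterministic.

## Allelic counting and bi-allelic filtration

Counting follows ASEReadCounter semantics: mapping quality >= 50, base
quality >= 25 at the site, duplicates and secondary/supplementary records
excluded, overlapping proper-pair mates counted once per fragment (mates
disagreeing at the site contribute nothing). Bases matching neither
catalogued allele are tallied as `otherBases` and never enter the ratio
denominator.

Filtration keeps a site iff `total >= 10`, `ref >= 3`, `alt >= 3`,
`ref/total >= 1%`, and `alt/total >= 1%`. The two allele-count rules
dominate until `total > 300`, past which the 1% rule binds (it exists to
catch rare-allele noise at very deep sites). The filter removes observed
mono-allelic expression without any allelic-ratio cutoff: with short-read
data and no parental genotypes, silence of one allele cannot be
distinguished from sequencing error, so such sites are excluded rather
than called. The filter is idempotent and sites at ratio exactly 0 or 1
are impossible downstream — the QC summary asserts this.

## Gene-level static ASE

Per SNV, the evidence against balance is the exact two-sided binomial
p-value of the ref count at `p = 0.5` (computed by the symmetric closed
form, identical to minimum-likelihood enumeration), folded to a
non-negative normal deviate `z = Phi^-1(1 - p/2)` and weighted by
`w = sqrt(depth)`. The gene score is the weighted Liptak-Stouffer
combination `sum(w z) / sqrt(sum(w^2))`; with equal weights this is
`sum(z)/sqrt(k)`. Direction is deliberately discarded: SNVs within a gene
are unphased, so imbalance magnitudes, not signs, are comparable.

Significance is empirical. The null model pools SNV depths from genes with
2–100 informative loci; for each needed SNV count `k` it draws `n_iter =
1e5` replicates of `k` depths (with replacement), regenerates ref counts
from `Binomial(depth, 0.5)`, and rebuilds the score. Resampling depths and
regenerating counts — rather than resampling observed counts — keeps true
ASE out of the null. The empirical p uses add-one smoothing
`(1 + #{null >= obs}) / (1 + n_iter)`, which is a valid p-value under
resampling and never exactly zero. Genes with `k` outside the pool range
are still tested against a null drawn for their `k`, flagged in the
output. Benjamini-Hochberg FDR across genes, significance at FDR < 0.1.

## Condition-dependent ASE

**SNV level.** For each site present (post-filtration) in both conditions,
the 2x2 table `[[ref_A, alt_A], [ref_B, alt_B]]` gets a two-sided Fisher's
exact p (minimum-likelihood hypergeometric enumeration; zero-margin tables
give p = 1). Sites shared by all individuals (identical chrom, pos, ref,
alt) are combined across individuals with the Stouffer method (equal
weights by default) and BH-corrected across sites, with significance tiers
at FDR < 1e-2 and < 1e-8.

One calibration subtlety: a discrete exact p-value has null expectation
above 1/2, so converting six of them to z-scores and summing produces a
systematically negative Z and badly conservative, non-uniform combined
p-values (measured KS distance 0.45 from uniform at depth ~100). The
z-conversion therefore uses Lancaster's mid-p — tables exactly as likely
as the observed one count half — whose null expectation is exactly 1/2;
the combined p's are then uniform to KS precision. The reported
per-individual p-values remain the exact Fisher p's, and with a single
individual the combination degenerates to the raw Fisher p identically.

**Gene level (ICD).** Per paired SNV the Fisher p is folded to a deviate
and aggregated over the gene with `sqrt(total depth)` Liptak-Stouffer
weights. The null regenerates both conditions' ref counts from
`Binomial(depth, p_hat)` with the pooled ref fraction
`p_hat = (ref_A + ref_B) / (n_A + n_B)` per SNV — so static imbalance that
does not change between conditions sits at the null's centre, and only a
shift is signal. Because per-condition depths are fixed within a gene, the
Fisher p for every replicate is a lookup in a precomputed
`(n_A + 1) x (n_B + 1)` p-value matrix, which is what makes `1e5`
replicates per gene affordable. The absolute log2 allelic-odds shift with
Haldane-Anscombe 0.5 pseudocounts is reported as a descriptive effect
size. An optional beta-binomial intra-class correlation `rho` in the
simulator (not the test) produces overdispersed counts for robustness
checks; the test's null itself is binomial.

The SNV-level and gene-level views deliberately disagree on diluted
signal: one strongly condition-dependent SNV among many static SNVs is
averaged away by the gene aggregate but stands out to the per-site Fisher
test combined across individuals. The acceptance suite reproduces this
contrast quantitatively.

## Sharing classification

A feature is *shared* when significant in at least `ceil(2/3 * n)` of the
available samples (4 of 6; still 4 of 5 when one sample failed QC —
the rule applies to samples actually present), *private* when significant
in exactly one, *female_only*/*male_only* when significant in every sample
of one sex and none of the other, otherwise *multi*. The order of those
checks makes the classification a partition. Across tissues, a feature
shared in exactly one tissue is tissue-specific, in all tissues pervasive,
otherwise multi-tissue. Mean effects average only the samples where the
feature is significant.

## Synthetic data

`simulate_counts` draws per-site depths (Poisson, mean 100 — the scale of
heterozygous-site coverage in deep bulk RNA-seq — or fixed) and ref counts
from `Binomial(depth, p)` or `Beta-Binomial(depth, p, rho)`. All SNVs of a
gene share its true ratio (a cis effect); effect genes shift it (default
0.7), condition genes shift it only in condition B, optionally at a subset
of their SNVs. `simulate_reads` builds a random toy genome whose reference
carries the ref alleles, two haplotypes per gene differing exactly at its
SNVs, and uniform single-end 125 bp reads drawn whole from one haplotype.
Mapping bias is planted by decoy contigs carrying the alternate-haplotype
window around chosen sites: alt reads covering the site match the decoy
perfectly and desert the gene locus under best-match alignment, exactly
the mechanism behind reference bias at paralogs. One global seed expands
into fixed per-component child streams (`SeedSequence` keyed by
`(seed, stream)`), so every stage is independently reproducible.

What the simulations do *not* model: sequencing error, quality decay, PCR
duplication beyond positional collision, splicing, indels, fragment-size
distributions, library-size variation, or genotyping error in the
catalog. Passing tests therefore demonstrate the statistical machinery and
the bias-removal logic, not robustness to those real-data artefacts.

## Numerical choices and degenerate inputs

- Exact binomial and Fisher p-values use log-gamma arithmetic; likelihood
  ties are resolved with the same relative tolerance (1e-7) scipy uses, and
  the implementations are tested cell-by-cell against scipy's
  `binomtest`/`fisher_exact` as independent oracles.
- p = 0 entering a Stouffer combination is clamped to the smallest positive
  double with a warning; p = 1 is clamped just below 1 so z stays finite.
- Empirical p-values can never be 0 (add-one smoothing); BH q-values are
  monotone by cumulative minimum from the largest p.
- Sites assigned to overlapping genes count in each gene; sites in no gene
  stay available to SNV-level analyses. Intronic and flank sites are
  included in gene aggregation by default, with an exon-only flag.
- Zero-depth sites are rejected before evidence construction; zero-margin
  Fisher tables return p = 1 (mid-p 1/2).
- Coordinates are 0-based half-open in memory; 1-based only in VCF/GFF
  readers/writers and the ASEReadCounter-convention count tables.

## Problem sizes in the acceptance script

The acceptance script regenerates everything at desk scale: 40 genes x 800
reads (~3e4 informative reads, sampling error of the global ratio mean
~0.003) for the bias-removal pass; 500–1000 features with `n_iter = 1e4`
for the calibration and FDR simulations; 50 replicates for the
model-contrast rate. These sizes keep each quantity's Monte-Carlo error
well inside the property bands it is checked against.

## Known limitations

- The toy aligner is substitution-only; spliced or gapped toy data would
  need the external-aligner shim.
- The ICD null conditions on the plug-in `p_hat` per SNV; at very low
  depths this slightly narrows the null (standard plug-in bootstrap
  behaviour), though calibration at the simulated depths is KS-clean.
- Stouffer combination treats individuals as independent; related animals
  would need an effective-sample-size correction.
- The sharing rules are descriptive set logic, not tests of sharing
  enrichment.
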