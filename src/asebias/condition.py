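"""Condition-dependent allele-specific expression.

Two complementary views of inducible imbalance between paired conditions
(e.g. unstimulated vs LPS-stimulated macrophages from the same animal):

* **SNV level** — a 2x2 Fisher's exact test of (ref, alt) counts between
  conditions per site and individual, Stouffer-combined across individuals
  at sites shared by all of them, then BH-corrected across sites.
* **Gene level (ICD)** — per-SNV Fisher evidence folded to non-negative
  deviates and aggregated over the gene with depth-weighted
  Liptak-Stouffer, tested against a gene-specific resampling null in which
  both conditions' ref counts are regenerated from Binomial(depth, p-hat)
  with the pooled ref fraction p-hat — i.e. allelic imbalance that does not
  change between conditions is null.

Each SNV also gets a descriptive effect size: the absolute log2 ratio of
the condition-B to condition-A allelic odds, with Haldane-Anscombe 0.5
pseudocounts guarding empty cells.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting import CountTable
from .stats import (
    bh_fdr,
    fisher_p_table,
    fisher_twosided,
    folded_z,
    liptak_stouffer,
    liptak_stouffer_rows,
    stouffer_combine,
)

N_ITER_DEFAULT = 100_000
FDR_THRESHOLD_DEFAULT = 0.1
TIERS_DEFAULT = (1e-2, 1e-8)

PAIRED_KEY = ["contig", "position", "variantID", "refAllele", "altAllele"]


@dataclass(frozen=True)
class PairedCount:
    """Ref/alt counts for one site in two paired conditions."""

    chrom: str
    pos1: int
    ref_a: int
    alt_a: int
    ref_b: int
    alt_b: int
    variant_id: str = ""

    def table(self):
        return [[self.ref_a, self.alt_a], [self.ref_b, self.alt_b]]


def pair_counts(table_a: CountTable, table_b: CountTable) -> pd.DataFrame:
    """Join two filtered count tables on identical sites.

    Only sites present (i.e. surviving bi-allelic filtration) in BOTH
    conditions with identical (chrom, pos, ref, alt) are paired. Columns:
    the site key plus ref_a/alt_a/ref_b/alt_b.
    """
    a = table_a.df[PAIRED_KEY + ["refCount", "altCount"]].rename(
        columns={"refCount": "ref_a", "altCount": "alt_a"})
    b = table_b.df[PAIRED_KEY + ["refCount", "altCount"]].rename(
        columns={"refCount": "ref_b", "altCount": "alt_b"})
    return a.merge(b, on=PAIRED_KEY, how="inner")


def fisher_per_snv(pc: PairedCount) -> float:
    """Two-sided Fisher's exact p for one paired-count site."""
    return float(fisher_twosided(pc.ref_a, pc.alt_a, pc.ref_b, pc.alt_b))


def log2_shift(ref_a, alt_a, ref_b, alt_b) -> np.ndarray:
    """|log2| change of allelic odds between conditions (0.5 pseudocounts)."""
    ref_a, alt_a, ref_b, alt_b = (np.asarray(x, dtype=float)
                                  for x in (ref_a, alt_a, ref_b, alt_b))
    odds_a = (ref_a + 0.5) / (alt_a + 0.5)
    odds_b = (ref_b + 0.5) / (alt_b + 0.5)
    return np.abs(np.log2(odds_b / odds_a))


# ---------------------------------------------------------------------------
# SNV-level: Fisher per individual -> Stouffer across individuals -> BH
# ---------------------------------------------------------------------------


def cd_snv_test(
    paired_by_individual: dict[str, pd.DataFrame],
    min_individuals: int | None = None,
    tiers=TIERS_DEFAULT,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Condition-dependent ASE at SNV level across individuals.

    Restricts to sites shared (identical chrom/pos/ref/alt) by at least
    ``min_individuals`` individuals (default: all of them), computes the
    per-individual Fisher p, combines per site with the Stouffer method,
    and BH-corrects across sites. Two-sided Fisher p-values enter the
    combination as evidence magnitudes; the direction of the shift is not
    compared across individuals, since allele phase is unknown.

    The per-individual column reports the exact Fisher p, but the Stouffer
    z conversion uses the corresponding mid-p (ties at half weight):
    discrete exact p-values have null expectation above 1/2, and combining
    six of them without the mid-p correction makes the combined p severely
    conservative and non-uniform under the null.

    Returns one row per shared site with per-individual p columns
    (``p_<individual>``), combined Z, combined p, fdr, and the
    significance tier index (number of ``tiers`` thresholds passed).
    """
    if not paired_by_individual:
        raise ValueError("no individuals supplied")
    individuals = sorted(paired_by_individual)
    need = len(individuals) if min_individuals is None else int(min_individuals)
    frames = []
    for ind in individuals:
        df = paired_by_individual[ind][PAIRED_KEY + ["ref_a", "alt_a", "ref_b", "alt_b"]]
        df = df.assign(individual=ind)
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    n_by_site = long.groupby(PAIRED_KEY)["individual"].nunique()
    shared = n_by_site[n_by_site >= need].index
    if len(shared) == 0:
        warnings.warn("no sites shared by the required number of individuals")
        return pd.DataFrame(
            columns=PAIRED_KEY + [f"p_{i}" for i in individuals]
            + ["n_individuals", "Z", "p_combined", "fdr", "tier"])
    long = long.set_index(PAIRED_KEY).loc[shared].reset_index()
    args = (long["ref_a"].to_numpy(), long["alt_a"].to_numpy(),
            long["ref_b"].to_numpy(), long["alt_b"].to_numpy())
    long["p_fisher"] = fisher_twosided(*args)
    long["p_mid"] = fisher_twosided(*args, mid=True)

    rows = []
    for key, grp in long.groupby(PAIRED_KEY, sort=True):
        p_by_ind = dict(zip(grp["individual"], grp["p_fisher"]))
        mid_by_ind = dict(zip(grp["individual"], grp["p_mid"]))
        present = [i for i in individuals if i in p_by_ind]
        ps = [p_by_ind[i] for i in present]
        w = [weights[i] for i in present] if weights else None
        if len(present) == 1:
            # nothing to combine: degenerate exactly to the Fisher p
            z, p_comb = stouffer_combine(ps, w)
        else:
            z, p_comb = stouffer_combine([mid_by_ind[i] for i in present], w)
        row = dict(zip(PAIRED_KEY, key))
        for ind in individuals:
            row[f"p_{ind}"] = p_by_ind.get(ind, np.nan)
        row.update(n_individuals=len(ps), Z=z, p_combined=p_comb)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_combined"].to_numpy())
    out["tier"] = sum((out["fdr"] < t).astype(int) for t in tiers)
    return out.sort_values("p_combined", ignore_index=True)


# ---------------------------------------------------------------------------
# Gene-level ICD
# ---------------------------------------------------------------------------


def _gene_groups(paired: pd.DataFrame,
                 gene_of: dict[tuple[str, int], list[str]]):
    by_gene: dict[str, list[int]] = {}
    for i, (chrom, pos1) in enumerate(zip(paired["contig"], paired["position"])):
        for gene in gene_of.get((chrom, pos1 - 1), []):
            by_gene.setdefault(gene, []).append(i)
    return {g: paired.iloc[idx] for g, idx in by_gene.items()}


def _icd_score(ref_a, alt_a, ref_b, alt_b) -> float:
    p = fisher_twosided(ref_a, alt_a, ref_b, alt_b)
    z = folded_z(p)
    w = np.sqrt((ref_a + alt_a + ref_b + alt_b).astype(float))
    return liptak_stouffer(z, w)


def _icd_null_scores(na, nb, p_hat, n_iter, rng) -> np.ndarray:
    """Null ICD scores for one gene: regenerate both conditions' ref counts
    from Binomial(depth, p_hat) per SNV and rescore; the Fisher p for each
    replicate is a table lookup since the per-condition depths are fixed."""
    k = len(na)
    z = np.empty((n_iter, k))
    for j in range(k):
        tab = fisher_p_table(int(na[j]), int(nb[j]))
        ra = rng.binomial(na[j], p_hat[j], size=n_iter)
        rb = rng.binomial(nb[j], p_hat[j], size=n_iter)
        z[:, j] = folded_z(tab[ra, rb])
    w = np.sqrt((na + nb).astype(float))
    return np.sort(liptak_stouffer_rows(z, np.broadcast_to(w, (n_iter, k))))


def icd_gene_test(
    paired: pd.DataFrame,
    gene_of: dict[tuple[str, int], list[str]],
    n_iter: int = N_ITER_DEFAULT,
    seed: int = 0,
    fdr_threshold: float = FDR_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Gene-level inducible (condition-dependent) ASE for one individual.

    Per gene: Fisher evidence at each paired SNV is folded and aggregated
    with sqrt(total-depth) Liptak-Stouffer weights; the empirical p comes
    from ``n_iter`` null replicates regenerated under a common ref fraction
    per SNV (no change between conditions); BH-FDR across genes. The mean
    absolute log2 odds shift is reported as a descriptive effect size.
    """
    groups = _gene_groups(paired, gene_of)
    rows = []
    for gene_id in sorted(groups):
        gdf = groups[gene_id]
        ra = gdf["ref_a"].to_numpy(np.int64)
        aa = gdf["alt_a"].to_numpy(np.int64)
        rb = gdf["ref_b"].to_numpy(np.int64)
        ab = gdf["alt_b"].to_numpy(np.int64)
        na, nb = ra + aa, rb + ab
        score = _icd_score(ra, aa, rb, ab)
        p_hat = (ra + rb) / (na + nb)
        rng = np.random.default_rng((seed, zlib.crc32(gene_id.encode())))
        null = _icd_null_scores(na, nb, p_hat, n_iter, rng)
        b = null.size - np.searchsorted(null, score, side="left")
        p_emp = (1 + b) / (1 + n_iter)
        shift = float(np.mean(log2_shift(ra, aa, rb, ab)))
        rows.append((gene_id, len(gdf), score, shift, p_emp))
    if not rows:
        return pd.DataFrame(columns=["gene_id", "n_snvs", "icd_score",
                                     "mean_log2_shift", "p_empirical", "fdr",
                                     "significant"])
    out = pd.DataFrame(rows, columns=["gene_id", "n_snvs", "icd_score",
                                      "mean_log2_shift", "p_empirical"])
    out["fdr"] = bh_fdr(out["p_empirical"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    return out.sort_values("icd_score", ascending=False, ignore_index=True)
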