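"""Gene-level static allele-specific expression.

Each informative SNV contributes evidence against balanced expression: an
exact two-sided binomial p-value versus a 0.5 allelic ratio, folded into a
non-negative normal deviate and weighted by the square root of its depth.
Per-gene evidence is aggregated with the weighted Liptak-Stouffer method;
significance comes from an empirical null built by resampling SNV depths
from a pool (genes with 2-100 informative loci) and regenerating counts
under Binomial(depth, 0.5), 1e5 replicates per SNV-count stratum. Direction
is discarded: the statistic measures magnitude of allelic imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting import CountTable
from .stats import (
    bh_fdr,
    binom_p_twosided_half,
    folded_z,
    liptak_stouffer,
    liptak_stouffer_rows,
)

N_ITER_DEFAULT = 100_000
FDR_THRESHOLD_DEFAULT = 0.1
POOL_K_RANGE = (2, 100)


@dataclass(frozen=True)
class SNVEvidence:
    """Imbalance evidence at one SNV: exact binomial p, folded z, sqrt-depth weight."""

    ref_count: int
    alt_count: int
    p_snv: float
    z_snv: float
    weight: float


def snv_evidence(ref_count: int, alt_count: int) -> SNVEvidence:
    total = ref_count + alt_count
    if total <= 0:
        raise ValueError("SNV evidence requires positive depth")
    p = float(binom_p_twosided_half(ref_count, total))
    return SNVEvidence(
        ref_count=ref_count, alt_count=alt_count, p_snv=p,
        z_snv=float(folded_z(p)), weight=float(np.sqrt(total)),
    )


def evidence_arrays(ref: np.ndarray, alt: np.ndarray):
    """Vectorised (p, z, weight) for arrays of ref/alt counts."""
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    total = ref + alt
    p = binom_p_twosided_half(ref, total)
    return p, folded_z(p), np.sqrt(total.astype(float))


def aggregate_gene(evidence: list[SNVEvidence]) -> float:
    """Weighted Liptak-Stouffer score over a gene's SNV evidence."""
    if not evidence:
        raise ValueError("cannot aggregate an empty evidence list")
    z = np.array([e.z_snv for e in evidence])
    w = np.array([e.weight for e in evidence])
    return liptak_stouffer(z, w)


def gene_counts(
    table: CountTable, gene_of: dict[tuple[str, int], list[str]]
) -> dict[str, pd.DataFrame]:
    """Group a filtered count table into per-gene count frames.

    ``gene_of`` maps (chrom, 0-based pos) to gene ids; sites assigned to
    several overlapping genes appear in each. Unassigned sites are left out
    (they remain available to SNV-level analyses).
    """
    by_gene: dict[str, list[int]] = {}
    df = table.df
    for i, (chrom, pos1) in enumerate(zip(df["contig"], df["position"])):
        for gene in gene_of.get((chrom, pos1 - 1), []):
            by_gene.setdefault(gene, []).append(i)
    return {g: df.iloc[idx] for g, idx in by_gene.items()}


class NullModel:
    """Resampled null distribution of the gene-level imbalance score.

    The pool holds SNV depths from genes with ``pool_k_range`` informative
    loci. For a gene with k SNVs, each null replicate samples k depths with
    replacement, draws ref counts ~ Binomial(depth, 0.5), rebuilds the
    folded-z evidence and aggregates — giving the score distribution of a
    balanced gene with realistic depths. Samples are cached per k and are
    reproducible under the seed.
    """

    def __init__(self, pool: np.ndarray, n_iter: int = N_ITER_DEFAULT,
                 seed: int = 0, pool_k_range=POOL_K_RANGE):
        pool = np.asarray(pool, dtype=np.int64)
        if pool.size == 0:
            raise ValueError(
                "empty depth pool: no gene has an SNV count inside "
                f"{pool_k_range}; relax the count filters or widen the range"
            )
        self.pool = pool
        self.n_iter = int(n_iter)
        self.seed = int(seed)
        self.pool_k_range = pool_k_range
        self._cache: dict[int, np.ndarray] = {}

    def samples(self, k: int) -> np.ndarray:
        """Sorted null score samples for genes with k informative SNVs."""
        if k not in self._cache:
            # independent child stream per k so cached entries do not depend
            # on the order in which k values were requested
            rng = np.random.default_rng((self.seed, k))
            depths = rng.choice(self.pool, size=(self.n_iter, k), replace=True)
            ref = rng.binomial(depths, 0.5)
            _, z, w = evidence_arrays(ref, depths - ref)
            self._cache[k] = np.sort(liptak_stouffer_rows(z, w))
        return self._cache[k]

    def p_empirical(self, score: float, k: int) -> float:
        """(b+1)/(n+1)-smoothed upper-tail empirical p; never exactly 0."""
        null = self.samples(k)
        b = null.size - np.searchsorted(null, score, side="left")
        return float((1 + b) / (1 + self.n_iter))


def build_null(
    table: CountTable,
    gene_of: dict[tuple[str, int], list[str]],
    n_iter: int = N_ITER_DEFAULT,
    seed: int = 0,
    pool_k_range=POOL_K_RANGE,
) -> NullModel:
    """Build the resampling null from a filtered table's depth pool."""
    pool = []
    for gene_df in gene_counts(table, gene_of).values():
        k = len(gene_df)
        if pool_k_range[0] <= k <= pool_k_range[1]:
            pool.extend(gene_df["totalCount"].tolist())
    return NullModel(np.asarray(pool), n_iter=n_iter, seed=seed,
                     pool_k_range=pool_k_range)


def static_test(
    table: CountTable,
    gene_of: dict[tuple[str, int], list[str]],
    null: NullModel | None = None,
    n_iter: int = N_ITER_DEFAULT,
    seed: int = 0,
    fdr_threshold: float = FDR_THRESHOLD_DEFAULT,
    min_k: int = 1,
) -> pd.DataFrame:
    """Test every gene for static ASE against the resampled null.

    Returns a frame (gene_id, n_snvs, score, p_empirical, fdr, significant)
    sorted by score, descending. Genes with fewer than ``min_k`` informative
    SNVs are skipped; genes with more SNVs than the null pool's upper k
    bound are still tested (a null is drawn for their k on demand) and
    flagged in the ``k_above_pool_range`` column.
    """
    per_gene = gene_counts(table, gene_of)
    if null is None:
        null = build_null(table, gene_of, n_iter=n_iter, seed=seed)
    rows = []
    for gene_id, gdf in per_gene.items():
        k = len(gdf)
        if k < min_k:
            continue
        _, z, w = evidence_arrays(
            gdf["refCount"].to_numpy(), gdf["altCount"].to_numpy()
        )
        score = liptak_stouffer(z, w)
        rows.append((gene_id, k, score, null.p_empirical(score, k),
                     k > null.pool_k_range[1]))
    if not rows:
        return pd.DataFrame(columns=["gene_id", "n_snvs", "score", "p_empirical",
                                     "fdr", "significant", "k_above_pool_range"])
    out = pd.DataFrame(rows, columns=["gene_id", "n_snvs", "score",
                                      "p_empirical", "k_above_pool_range"])
    out["fdr"] = bh_fdr(out["p_empirical"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    out = out.sort_values("score", ascending=False, ignore_index=True)
    return out[["gene_id", "n_snvs", "score", "p_empirical", "fdr",
                "significant", "k_above_pool_range"]]
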