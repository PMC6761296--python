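"""Shared statistical primitives for allelic-imbalance testing.

Everything here is vectorised because the resampling nulls evaluate these
functions millions of times: exact two-sided binomial p-values against an
allelic ratio of 0.5, two-sided Fisher's exact p-values by hypergeometric
enumeration (cached as lookup tables keyed by the fixed per-condition
depths), folded-normal evidence conversion, weighted Liptak-Stouffer
aggregation, Stouffer meta-combination, and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import functools
import warnings

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

# Smallest p we propagate into inverse-normal transforms; avoids infinities
# without materially changing any z in double precision.
_TINY_P = 1e-300
# A p of exactly 1 maps to z = -inf under the one-sided inverse normal;
# clamp just below 1 instead (Phi^-1 of 1 - 1e-16 ~ -8.2).
_ONE_MINUS = 1.0 - 1e-16


def binom_p_twosided_half(ref: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Exact two-sided binomial p-value of ``ref`` successes in ``total``
    trials under p = 0.5.

    By the symmetry of Binomial(n, 1/2) the minimum-likelihood two-sided
    p-value equals twice the smaller tail, capped at 1, which lets the whole
    table be evaluated in one vectorised CDF call. Matches
    ``scipy.stats.binomtest(k, n, 0.5)`` exactly.
    """
    ref = np.asarray(ref)
    total = np.asarray(total)
    if np.any(total <= 0):
        raise ValueError("total depth must be positive")
    minor = np.minimum(ref, total - ref)
    p = 2.0 * stats.binom.cdf(minor, total, 0.5)
    # when total is even and ref == total/2 the doubling overshoots 1
    return np.minimum(p, 1.0)


def folded_z(p: np.ndarray) -> np.ndarray:
    """Fold a two-sided p-value into a non-negative normal deviate.

    z = Phi^-1(1 - p/2); perfect balance (p = 1) gives z = 0. Direction of
    imbalance is deliberately discarded: the gene-level statistic measures
    magnitude of allelic imbalance, and alleles are unphased across SNVs.
    """
    p = np.clip(np.asarray(p, dtype=float), _TINY_P, 1.0)
    return np.maximum(stats.norm.isf(p / 2.0), 0.0)


def liptak_stouffer(z: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted Liptak-Stouffer aggregate: sum(w*z) / sqrt(sum(w^2)).

    With equal weights this reduces to sum(z)/sqrt(k). Invariant under
    uniform rescaling of the weights.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim == 0:
        z = z[None]
    if z.size == 0:
        raise ValueError("cannot aggregate an empty evidence list")
    if weights is None:
        weights = np.ones_like(z)
    w = np.asarray(weights, dtype=float)
    if w.shape != z.shape:
        raise ValueError("weights and z must have the same shape")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(w * z) / np.sqrt(np.sum(w * w)))


def liptak_stouffer_rows(z: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Row-wise Liptak-Stouffer over a (replicates, k) matrix."""
    z = np.asarray(z, dtype=float)
    if weights is None:
        return z.sum(axis=-1) / np.sqrt(z.shape[-1])
    w = np.asarray(weights, dtype=float)
    return (w * z).sum(axis=-1) / np.sqrt((w * w).sum(axis=-1))


def stouffer_combine(
    p_values, weights=None
) -> tuple[float, float]:
    """Combine one-per-study p-values with the Stouffer method.

    z_i = Phi^-1(1 - p_i), Z = sum(w z)/sqrt(sum(w^2)), combined p is the
    upper normal tail of Z. p_i = 0 is clamped to the smallest positive
    double with a warning; p_i = 1 is clamped just below 1 so z stays finite.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim == 0:
        p = p[None]
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to smallest positive value")
    p = np.clip(p, _TINY_P, _ONE_MINUS)
    z = stats.norm.isf(p)
    if weights is None:
        weights = np.ones_like(z)
    w = np.asarray(weights, dtype=float)
    zc = float(np.sum(w * z) / np.sqrt(np.sum(w * w)))
    return zc, float(stats.norm.sf(zc))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone from the largest p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Fisher's exact test by hypergeometric enumeration
# ---------------------------------------------------------------------------

# scipy uses the same relative tolerance when summing tables at least as
# extreme as the observed one; keeping it makes the enumeration agree with
# fisher_exact to the last ulp in practice.
_REL_TOL = 1.0 + 1e-7


@functools.lru_cache(maxsize=4096)
def fisher_p_table(n_a: int, n_b: int, mid: bool = False) -> np.ndarray:
    """Two-sided Fisher's exact p for every 2x2 table with fixed row sums.

    Returns a matrix ``P`` of shape (n_a+1, n_b+1) where ``P[ra, rb]`` is the
    two-sided p-value of the table [[ra, n_a-ra], [rb, n_b-rb]] (the
    minimum-likelihood rule: sum of hypergeometric probabilities not larger
    than the observed table's). Row sums are the per-condition depths, so the
    table is reusable across every site and null replicate with those depths.

    With ``mid=True`` the tables exactly as likely as the observed one
    (including itself) contribute half weight — Lancaster's mid-p, whose
    null expectation is 1/2 despite the discreteness. Degenerate margins
    give p = 1 (mid-p = 1/2): no information.
    """
    if n_a < 0 or n_b < 0:
        raise ValueError("depths must be non-negative")
    out = np.full((n_a + 1, n_b + 1), 0.5 if mid else 1.0)
    n = n_a + n_b
    lgam = special.gammaln
    for m in range(n + 1):  # m = total ref reads across conditions
        lo = max(0, m - n_b)
        hi = min(m, n_a)
        a = np.arange(lo, hi + 1)
        logpmf = (
            lgam(n_a + 1) - lgam(a + 1) - lgam(n_a - a + 1)
            + lgam(n_b + 1) - lgam(m - a + 1) - lgam(n_b - m + a + 1)
            - (lgam(n + 1) - lgam(m + 1) - lgam(n - m + 1))
        )
        pmf = np.exp(logpmf)
        order = np.argsort(pmf)
        sorted_pmf = pmf[order]
        csum = np.cumsum(sorted_pmf)
        # p(a_obs) = sum of pmf over tables with pmf <= pmf(a_obs)*(1+eps)
        idx = np.searchsorted(sorted_pmf, pmf * _REL_TOL, side="right")
        pvals = np.minimum(csum[np.maximum(idx, 1) - 1], 1.0)
        if mid:
            # subtract half the probability mass of the ties (incl. observed)
            lo_idx = np.searchsorted(sorted_pmf, pmf / _REL_TOL, side="left")
            below = np.where(lo_idx > 0, csum[np.maximum(lo_idx, 1) - 1], 0.0)
            pvals = below + 0.5 * (pvals - below)
        out[a, m - a] = pvals
    return out


def fisher_twosided(ref_a, alt_a, ref_b, alt_b, mid: bool = False) -> np.ndarray:
    """Two-sided Fisher's exact p for tables [[ref_a, alt_a], [ref_b, alt_b]].

    Scalar or array inputs; any table with a zero margin returns 1 (the
    conditional distribution is degenerate, so the data carry no
    association information). ``mid=True`` gives Lancaster's mid-p.
    """
    ra = np.atleast_1d(np.asarray(ref_a, dtype=np.int64))
    aa = np.atleast_1d(np.asarray(alt_a, dtype=np.int64))
    rb = np.atleast_1d(np.asarray(ref_b, dtype=np.int64))
    ab = np.atleast_1d(np.asarray(alt_b, dtype=np.int64))
    if np.any((ra < 0) | (aa < 0) | (rb < 0) | (ab < 0)):
        raise ValueError("counts must be non-negative")
    na = ra + aa
    nb = rb + ab
    out = np.ones(ra.shape)
    for key in set(zip(na.tolist(), nb.tolist())):
        table = fisher_p_table(*key, mid=mid)
        mask = (na == key[0]) & (nb == key[1])
        out[mask] = table[ra[mask], rb[mask]]
    if np.isscalar(ref_a) or np.ndim(ref_a) == 0:
        return float(out[0])
    return out
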