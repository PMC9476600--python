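"""Genomic inflation control and empirical condFDR / conjFDR estimation.

The conditional FDR of a SNP for a primary trait, given a conditional
trait, is cFDR(p_i | p_j) = Pr(H0_i | P_i <= p_i, P_j <= p_j): the
probability that the SNP is null for the primary trait given both observed
p-values.  With the null fraction conservatively set to 1 it is estimated
empirically from the bivariate empirical CDF,

    cFDR_hat[k] = p_i[k] * #{m : p_j[m] <= p_j[k]}
                          / #{m : p_i[m] <= p_i[k] and p_j[m] <= p_j[k]},

i.e. the expected null count among SNPs at least as extreme in the primary
trait, within the stratum selected by the conditional trait, divided by the
observed count.  The conjunctional FDR (ccFDR) for association with BOTH
traits is the maximum of the two reciprocal cFDRs — a conservative bound.

Thresholds are inclusive and every SNP counts itself, so the denominator is
always >= 1.  Estimates are capped at 1 and post-processed to be monotone
non-decreasing in the primary p-value at equal-or-looser conditioning
(a running maximum over the dominated quadrant), the standard cleanup for
empirical-CDF ratio estimators.

Before estimation each trait's p-values may be corrected for genomic
inflation: lambda = median(chi2_1(p)) / median of the chi2_1 distribution,
and p' is the chi-square tail probability of the deflated statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedPair

#: median of the chi-square distribution with one degree of freedom
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

_P_FLOOR = 1e-300


@dataclass
class GcReport:
    """Genomic inflation factor estimated from one trait's p-values."""

    lam: float
    n_used: int


@dataclass
class CfdrResult:
    """Per-SNP conditional and conjunctional FDR, aligned to a HarmonizedPair."""

    snp_ids: np.ndarray
    cfdr_a_given_b: np.ndarray
    cfdr_b_given_a: np.ndarray
    ccfdr: np.ndarray
    gc_a: GcReport | None = None
    gc_b: GcReport | None = None
    p_a_gc: np.ndarray | None = None
    p_b_gc: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.snp_ids)


def _check_pvals(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def genomic_control_lambda(pvals) -> GcReport:
    """Median-chi-square genomic inflation factor.

    Each p-value is converted to a 1-df chi-square statistic through the
    inverse upper-tail CDF; lambda is the observed median divided by the
    null median (~0.4549).  lambda ~ 1 under the null, > 1 under inflation.
    """
    p = _check_pvals(pvals)
    chi2 = stats.chi2.isf(p, 1)
    return GcReport(lam=float(np.median(chi2) / CHI2_1_MEDIAN), n_used=p.size)


def gc_correct(pvals, lam: float) -> np.ndarray:
    """Deflate p-values by a genomic inflation factor.

    p' = upper-tail chi2_1 probability of chi2_1(p)/lambda.  Factors below 1
    are clamped to 1 (genomic control never sharpens p-values); the SNP
    ranking by p is preserved.
    """
    p = _check_pvals(pvals)
    lam = max(float(lam), 1.0)
    if lam == 1.0:
        return p.copy()
    corrected = stats.chi2.sf(stats.chi2.isf(p, 1) / lam, 1)
    return np.clip(corrected, _P_FLOOR, 1.0)


def _dominated_counts(p_primary: np.ndarray, p_cond: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each k: (#{p_cond <= p_cond[k]}, #{both coords <=}), inclusive.

    Joint counts use a Fenwick tree over primary ranks while sweeping SNPs
    in order of the conditional p-value; ties on the conditional axis are
    inserted as a block before any member of the block is queried, so tied
    SNPs share identical counts.
    """
    n = p_primary.size
    # conditional marginal count = max rank among ties
    order_c = np.argsort(p_cond, kind="mergesort")
    sorted_c = p_cond[order_c]
    cond_count = np.empty(n, dtype=np.int64)
    cond_count[order_c] = np.searchsorted(sorted_c, sorted_c, side="right")

    prim_rank = np.searchsorted(np.sort(p_primary), p_primary, side="left")  # 0-based dense-ish
    tree = np.zeros(n + 1, dtype=np.int64)

    def update(i: int) -> None:
        i += 1
        while i <= n:
            tree[i] += 1
            i += i & (-i)

    def query(i: int) -> int:  # count of inserted ranks <= i
        i += 1
        s = 0
        while i > 0:
            s += tree[i]
            i -= i & (-i)
        return s

    # highest primary rank with value <= p_primary[k] (inclusive ties)
    prim_rank_hi = np.searchsorted(np.sort(p_primary), p_primary, side="right") - 1

    joint = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j < n and sorted_c[j] == sorted_c[i]:
            j += 1
        block = order_c[i:j]
        for k in block:
            update(int(prim_rank[k]))
        for k in block:
            joint[k] = query(int(prim_rank_hi[k]))
        i = j
    return cond_count, joint


def empirical_cfdr(p_primary, p_cond) -> np.ndarray:
    """Empirical conditional FDR of the primary trait given the conditional.

    With vacuous conditioning (``p_cond`` identically 1) this reduces to the
    unconditional empirical FDR p[k] * n / rank(p[k]) — the familiar
    step-up quantity of multiple-testing corrections.
    """
    p_primary = _check_pvals(p_primary)
    p_cond = _check_pvals(p_cond)
    if p_primary.shape != p_cond.shape:
        raise ValueError("p_primary and p_cond must have the same length")
    cond_count, joint = _dominated_counts(p_primary, p_cond)
    return np.minimum(p_primary * cond_count / joint, 1.0)


def empirical_cfdr_bruteforce(p_primary, p_cond) -> np.ndarray:
    """Direct O(n^2) evaluation of the same estimator (small n only)."""
    p_primary = _check_pvals(p_primary)
    p_cond = _check_pvals(p_cond)
    out = np.empty(p_primary.size)
    for k in range(p_primary.size):
        in_stratum = p_cond <= p_cond[k]
        joint = np.sum((p_primary <= p_primary[k]) & in_stratum)
        out[k] = min(p_primary[k] * np.sum(in_stratum) / joint, 1.0)
    return out


def enforce_monotone(cfdr, p_primary, p_cond, mode: str = "auto", grid_size: int = 512) -> np.ndarray:
    """Running maximum over the dominated quadrant of (p_primary, p_cond).

    Output[k] = max{ cfdr[m] : p_primary[m] <= p_primary[k] and
    p_cond[m] <= p_cond[k] }, so the estimate never decreases as the primary
    p-value grows at equal-or-looser conditioning.  ``mode='exact'``
    evaluates the quadrant maximum per SNP (quadratic; fine to ~10,000
    SNPs); ``mode='grid'`` bins both axes into ``grid_size`` quantile bins,
    takes per-cell maxima and a 2-D cumulative maximum, then looks each SNP
    up in its cell.  ``'auto'`` picks exact for n <= 10,000.
    """
    cfdr = np.asarray(cfdr, dtype=float)
    p_primary = np.asarray(p_primary, dtype=float)
    p_cond = np.asarray(p_cond, dtype=float)
    if not (cfdr.shape == p_primary.shape == p_cond.shape):
        raise ValueError("cfdr, p_primary, p_cond must be aligned")
    n = cfdr.size
    if mode == "auto":
        mode = "exact" if n <= 10_000 else "grid"

    if mode == "exact":
        out = np.empty(n)
        chunk = max(1, 2_000_000 // max(n, 1))
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            dom = (p_primary[None, :] <= p_primary[lo:hi, None]) & (
                p_cond[None, :] <= p_cond[lo:hi, None]
            )
            out[lo:hi] = np.where(dom, cfdr[None, :], -np.inf).max(axis=1)
        return np.minimum(out, 1.0)

    if mode != "grid":
        raise ValueError(f"unknown mode {mode!r}")

    # quantile-bin both axes; equal values share a bin so ties stay together
    def bins(x: np.ndarray) -> np.ndarray:
        qs = np.quantile(x, np.linspace(0, 1, grid_size + 1)[1:-1])
        return np.searchsorted(qs, x, side="left")

    bi, bj = bins(p_primary), bins(p_cond)
    cell = np.full((grid_size, grid_size), -np.inf)
    np.maximum.at(cell, (bi, bj), cfdr)
    np.maximum.accumulate(cell, axis=0, out=cell)
    np.maximum.accumulate(cell, axis=1, out=cell)
    return np.minimum(cell[bi, bj], 1.0)


def conjunction_fdr(cfdr_ab, cfdr_ba) -> np.ndarray:
    """Conjunctional FDR: elementwise maximum of the two reciprocal cFDRs.

    Taking the larger of cFDR(A|B) and cFDR(B|A) bounds the FDR for a SNP
    claimed to be associated with both traits.
    """
    cfdr_ab = np.asarray(cfdr_ab, dtype=float)
    cfdr_ba = np.asarray(cfdr_ba, dtype=float)
    if cfdr_ab.shape != cfdr_ba.shape:
        raise ValueError("cFDR vectors must have the same length")
    return np.maximum(cfdr_ab, cfdr_ba)


def run_cfdr(
    pair: HarmonizedPair,
    gc: bool = True,
    monotone: bool = True,
    mode: str = "auto",
) -> CfdrResult:
    """Full condFDR/conjFDR pipeline on a harmonized pair.

    Optionally applies genomic control to each trait, computes both
    reciprocal conditional FDRs (with monotone cleanup) and their
    conjunction.
    """
    p_a, p_b = pair.p_a, pair.p_b
    gc_a = gc_b = None
    if gc:
        gc_a = genomic_control_lambda(p_a)
        gc_b = genomic_control_lambda(p_b)
        p_a = gc_correct(p_a, gc_a.lam)
        p_b = gc_correct(p_b, gc_b.lam)

    cfdr_ab = empirical_cfdr(p_a, p_b)
    cfdr_ba = empirical_cfdr(p_b, p_a)
    if monotone:
        cfdr_ab = enforce_monotone(cfdr_ab, p_a, p_b, mode=mode)
        cfdr_ba = enforce_monotone(cfdr_ba, p_b, p_a, mode=mode)

    return CfdrResult(
        snp_ids=pair.snp_ids,
        cfdr_a_given_b=cfdr_ab,
        cfdr_b_given_a=cfdr_ba,
        ccfdr=conjunction_fdr(cfdr_ab, cfdr_ba),
        gc_a=gc_a,
        gc_b=gc_b,
        p_a_gc=p_a,
        p_b_gc=p_b,
    )


def ccfdr_table(pair: HarmonizedPair, result: CfdrResult) -> pd.DataFrame:
    """Per-SNP results as a tidy frame (the canonical ccfdr.tsv layout)."""
    return pd.DataFrame(
        {
            "snp_id": pair.snp_ids,
            "chrom": pair.chrom,
            "pos": pair.pos,
            "p_a": pair.p_a,
            "p_b": pair.p_b,
            "p_a_gc": result.p_a_gc if result.p_a_gc is not None else pair.p_a,
            "p_b_gc": result.p_b_gc if result.p_b_gc is not None else pair.p_b,
            "cfdr_a_given_b": result.cfdr_a_given_b,
            "cfdr_b_given_a": result.cfdr_b_given_a,
            "ccfdr": result.ccfdr,
        }
    )
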