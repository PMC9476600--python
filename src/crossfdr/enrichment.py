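"""Conditional (stratified) Q-Q curves and cross-trait fold enrichment.

Cross-trait enrichment shows up as a leftward/upward shift of the primary
trait's Q-Q curve within SNP strata selected by increasingly significant
p-values in the conditional trait.  The fold-enrichment curve makes the
shift quantitative: at a nominal threshold t on the -log10(p) axis,

    fold(stratum, t) = tail fraction of the stratum at t
                       / tail fraction of the all-SNP baseline at t,

so the baseline is identically 1 and an enriched stratum rises above it.
Curves are computed in both conditioning directions (A|B and B|A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import HarmonizedPair

DEFAULT_CUTOFFS = (1.0, 0.1, 0.01, 0.001)


@dataclass(frozen=True)
class StratumSpec:
    """Nested conditional p-value cutoffs; the first (=1) is the baseline."""

    cutoffs: tuple = DEFAULT_CUTOFFS

    def __post_init__(self):
        c = tuple(float(x) for x in self.cutoffs)
        if not c or c[0] != 1.0:
            raise ValueError("first cutoff must be 1 (baseline stratum)")
        if any(b >= a for a, b in zip(c, c[1:])):
            raise ValueError(f"cutoffs must be strictly decreasing, got {c}")
        object.__setattr__(self, "cutoffs", c)


@dataclass
class EnrichmentCurve:
    """Fold enrichment of one conditional stratum over a -log10(p) grid."""

    stratum_cutoff: float
    grid: np.ndarray
    fold: np.ndarray
    n_stratum: int
    n_exceed: np.ndarray = field(default=None)


def _select(pair: HarmonizedPair, primary: str) -> tuple[np.ndarray, np.ndarray]:
    """Primary/conditional p-vectors for a trait selector ('a' or 'b')."""
    if primary in ("a", pair.trait_a):
        return pair.p_a, pair.p_b
    if primary in ("b", pair.trait_b):
        return pair.p_b, pair.p_a
    raise ValueError(f"unknown primary trait selector {primary!r}")


def stratify(pair: HarmonizedPair, primary: str = "a", spec: StratumSpec | None = None) -> dict:
    """Index sets of SNPs whose conditional p-value passes each cutoff.

    The sets are nested: a stricter cutoff selects a subset of a looser
    one.  An empty stratum is flagged with a warning and omitted.
    """
    if len(pair) == 0:
        raise ValueError("empty pair")
    spec = spec or StratumSpec()
    _, p_cond = _select(pair, primary)
    out = {}
    for c in spec.cutoffs:
        idx = np.flatnonzero(p_cond <= c)
        if idx.size == 0:
            warnings.warn(f"stratum p_cond <= {c} is empty; omitted")
            continue
        out[c] = idx
    return out


def qq_curve(pvals) -> tuple[np.ndarray, np.ndarray]:
    """Nominal vs empirical -log10(p) pairs for a Q-Q plot.

    For order statistics p(1) <= ... <= p(n) the empirical quantile of rank
    r is r/(n+1) (which keeps -log10 finite at the extremes).  Returns the
    nominal values sorted ascending with the matching empirical quantiles;
    under uniform p-values the curve lies on the identity line.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    ranks = np.arange(1, n + 1)
    nominal = -np.log10(np.sort(p))          # descending in rank -> ascending order below
    empirical = -np.log10(ranks / (n + 1.0))
    # rank r pairs with the r-th smallest p; sort pairs by ascending nominal
    return nominal[::-1], empirical[::-1]


def fold_enrichment_curves(
    pair: HarmonizedPair,
    primary: str = "a",
    spec: StratumSpec | None = None,
    grid: np.ndarray | None = None,
    min_baseline_exceed: int = 10,
) -> list[EnrichmentCurve]:
    """Fold-enrichment curve per conditional stratum.

    The grid defaults to 101 equally spaced points on [0, min(10, max
    nominal -log10 p)].  Grid points where the baseline tail count drops
    below ``min_baseline_exceed`` are trimmed (the ratio of two vanishing
    tail fractions is noise, not signal).
    """
    spec = spec or StratumSpec()
    p_primary, _ = _select(pair, primary)
    strata = stratify(pair, primary, spec)
    if 1.0 not in strata:
        raise ValueError("baseline stratum is empty")

    neglog = -np.log10(p_primary)
    if grid is None:
        grid = np.linspace(0.0, min(10.0, float(neglog.max())), 101)
    grid = np.asarray(grid, dtype=float)

    base = np.sort(neglog[strata[1.0]])
    n_base = base.size
    base_exceed = n_base - np.searchsorted(base, grid, side="left")
    ok = base_exceed >= min_baseline_exceed

    curves = []
    for cutoff, idx in strata.items():
        vals = np.sort(neglog[idx])
        n_s = vals.size
        exceed = n_s - np.searchsorted(vals, grid, side="left")
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = (exceed / n_s) / (base_exceed / n_base)
        curves.append(
            EnrichmentCurve(
                stratum_cutoff=cutoff,
                grid=grid[ok],
                fold=fold[ok],
                n_stratum=n_s,
                n_exceed=exceed[ok],
            )
        )
    return curves


def curves_to_frame(curves: list[EnrichmentCurve]) -> pd.DataFrame:
    """Long-format table of enrichment curves (one row per stratum x grid point)."""
    rows = []
    for c in curves:
        rows.append(
            pd.DataFrame(
                {
                    "stratum_cutoff": c.stratum_cutoff,
                    "grid_t": c.grid,
                    "fold": c.fold,
                    "n_stratum": c.n_stratum,
                    "n_exceed": c.n_exceed,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def plot_fold_enrichment(curves: list[EnrichmentCurve], ax=None, title: str | None = None):
    """Render fold-enrichment curves (thin optional layer over the tables)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for c in curves:
        label = "baseline" if c.stratum_cutoff == 1.0 else f"p_cond <= {c.stratum_cutoff:g}"
        ax.plot(c.grid, c.fold, label=label)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(r"nominal $-\log_{10}(p)$, primary trait")
    ax.set_ylabel("fold enrichment")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
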