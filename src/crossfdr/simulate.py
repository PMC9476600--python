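"""Synthetic paired GWAS summary statistics with known pleiotropic structure.

The generator draws every SNP from a four-groups mixture — null in both
traits, non-null in trait A only, in trait B only, or in both ("shared") —
which is the two-groups z-score model underlying empirical cFDR methods,
extended to two traits.  A null SNP has z ~ N(0, 1); a non-null SNP gets
extra effect variance, z ~ N(0, 1 + sigma2).  Two-sided p-values follow as
p = 2 * (1 - Phi(|z|)).  Optional multiplicative inflation of z^2 emulates
confounding that genomic control should detect and remove, and a duplicate
fraction plants repeated rsIDs to exercise ingest-time deduplication.

Ground truth labels are returned alongside the two tables so calibration
(false-sharing proportion) and power (sensitivity for planted shared SNPs)
can be measured exactly downstream.

SNPs are independent and placed at unit spacing on a single synthetic
chromosome: the locus logic downstream needs coordinates, not linkage
realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumstatsTable

CLASSES = ("null", "a_only", "b_only", "shared")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the four-groups two-trait generator.

    Fractions ``pi_null + pi_a_only + pi_b_only + pi_shared`` must sum to 1.
    ``sigma2_a``/``sigma2_b`` are the extra effect variances added to the
    unit sampling variance for SNPs non-null in that trait; ``lambda_a``/
    ``lambda_b`` multiply z^2 (inflation, must be >= 1); ``dup_fraction``
    is the fraction of rsIDs emitted twice.
    """

    n_snps: int = 100_000
    pi_null: float = 0.95
    pi_a_only: float = 0.02
    pi_b_only: float = 0.02
    pi_shared: float = 0.01
    sigma2_a: float = 25.0
    sigma2_b: float = 25.0
    lambda_a: float = 1.0
    lambda_b: float = 1.0
    dup_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.pi_null, self.pi_a_only, self.pi_b_only, self.pi_shared)
        if any(f < 0 for f in fracs):
            raise ValueError(f"mixture fractions must be >= 0, got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-12:
            raise ValueError(f"mixture fractions must sum to 1, got {sum(fracs)!r}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.sigma2_a < 0 or self.sigma2_b < 0:
            raise ValueError("effect variances must be >= 0")
        if self.lambda_a < 1 or self.lambda_b < 1:
            raise ValueError("inflation factors must be >= 1")
        if not 0 <= self.dup_fraction < 1:
            raise ValueError("dup_fraction must be in [0, 1)")


@dataclass
class TruthLabels:
    """Per-SNP ground-truth class, aligned with the generated rsIDs."""

    snp_ids: np.ndarray
    labels: np.ndarray  # strings from CLASSES

    def __len__(self) -> int:
        return len(self.labels)

    def mask(self, *classes: str) -> np.ndarray:
        return np.isin(self.labels, classes)


def z_to_p(z) -> np.ndarray | float:
    """Two-sided p-value of a standard-normal z score, clamped to (0, 1].

    p = 2 * (1 - Phi(|z|)), evaluated through the survival function so the
    far tail does not underflow to 0 before the clamp.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z scores must be finite")
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return p if p.ndim else float(p)


def _draw_z(rng: np.random.Generator, nonnull: np.ndarray, sigma2: float, lam: float) -> np.ndarray:
    sd = np.where(nonnull, np.sqrt(1.0 + sigma2), 1.0)
    z = rng.standard_normal(nonnull.size) * sd
    if lam > 1.0:
        z = z * np.sqrt(lam)  # multiplies z^2 by lambda
    return z


def simulate_pair(config: SimConfig) -> tuple[SumstatsTable, SumstatsTable, TruthLabels]:
    """Draw one paired dataset; deterministic given ``config.seed``.

    Returns trait-A and trait-B tables in canonical form plus the truth
    labels for the ``n_snps`` unique SNPs.  When ``dup_fraction > 0`` a
    random subset of rsIDs appears twice, the second copy carrying an
    independent p-value draw from the same truth class.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_snps

    probs = [config.pi_null, config.pi_a_only, config.pi_b_only, config.pi_shared]
    classes = rng.choice(len(CLASSES), size=n, p=probs)
    labels = np.array(CLASSES, dtype=object)[classes]

    nonnull_a = (labels == "a_only") | (labels == "shared")
    nonnull_b = (labels == "b_only") | (labels == "shared")
    p_a = z_to_p(_draw_z(rng, nonnull_a, config.sigma2_a, config.lambda_a))
    p_b = z_to_p(_draw_z(rng, nonnull_b, config.sigma2_b, config.lambda_b))

    snp_ids = np.array([f"rs{i + 1}" for i in range(n)], dtype=object)
    pos = np.arange(1, n + 1, dtype=np.int64)

    def build(pvals: np.ndarray, trait: str, nonnull: np.ndarray, sigma2: float, lam: float):
        df = pd.DataFrame(
            {"snp_id": snp_ids, "chrom": "1", "pos": pos, "pvalue": pvals}
        )
        if config.dup_fraction > 0:
            k = int(round(config.dup_fraction * n))
            idx = rng.choice(n, size=k, replace=False)
            extra = df.iloc[idx].copy()
            extra["pvalue"] = z_to_p(_draw_z(rng, nonnull[idx], sigma2, lam))
            df = pd.concat([df, extra], ignore_index=True)
        return SumstatsTable(trait_name=trait, df=df, meta={"simulated": True})

    table_a = build(p_a, "trait_a", nonnull_a, config.sigma2_a, config.lambda_a)
    table_b = build(p_b, "trait_b", nonnull_b, config.sigma2_b, config.lambda_b)
    return table_a, table_b, TruthLabels(snp_ids=snp_ids, labels=labels)
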