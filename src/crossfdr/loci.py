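"""Shared-locus calling, nearest-gene annotation and reporting.

A shared (pleiotropic) locus is a SNP whose conjunctional FDR falls below
the calling threshold (default 0.01) while being suggestively significant
(p < 1e-5) in *both* traits.  Calling here is SNP-level: no LD clumping is
applied by default, matching analyses that report each passing SNP as a
locus; a greedy window-based clump is available as a convenience.

Annotation assigns each called SNP the gene(s) whose interval contains it,
or otherwise the nearest gene(s) by interval distance, with exact ties
reported together ("SPI1, MYBPC3" style).  Annotations come from BED
(0-based half-open, converted on read) or GFF3 ``gene`` features (1-based
inclusive, symbol from the ``Name=`` attribute).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cfdr import CfdrResult
from .sumstats import HarmonizedPair, _chrom_sort_key


@dataclass
class SharedLocus:
    """One called pleiotropic SNP with its ccFDR and gene assignment."""

    snp_id: str
    chrom: str
    pos: int
    ccfdr: float
    p_a: float | None = None
    p_b: float | None = None
    closest_genes: list = field(default_factory=list)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval, 1-based inclusive coordinates."""

    gene_symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self):
        if not self.gene_symbol:
            raise ValueError("empty gene symbol")
        if self.start > self.end or self.start < 1:
            raise ValueError(
                f"malformed interval {self.gene_symbol}: {self.start}-{self.end}"
            )

    def distance_to(self, pos: int) -> int:
        """0 inside the interval, else the gap to the nearer edge."""
        return max(self.start - pos, pos - self.end, 0)


def read_gene_annotations(path: str, fmt: str | None = None) -> list[GeneAnnotation]:
    """Load gene intervals from a BED or GFF3 file.

    BED is 0-based half-open and converted to 1-based inclusive; GFF3 is
    taken as-is (``gene`` features only, symbol from the ``Name``
    attribute).  ``fmt`` defaults from the file extension.
    """
    import pyranges as pr

    if fmt is None:
        low = path.lower()
        fmt = "gff3" if low.endswith((".gff", ".gff3")) else "bed"
    if fmt == "bed":
        df = pr.read_bed(path).df
        genes = [
            GeneAnnotation(
                gene_symbol=str(r.Name),
                chrom=str(r.Chromosome),
                start=int(r.Start) + 1,
                end=int(r.End),
                strand=str(getattr(r, "Strand", "unknown")),
            )
            for r in df.itertuples()
        ]
    elif fmt == "gff3":
        df = pr.read_gff3(path).df
        df = df[df["Feature"] == "gene"]
        # pyranges converts GFF3 to 0-based half-open internally
        genes = [
            GeneAnnotation(
                gene_symbol=str(r.Name),
                chrom=str(r.Chromosome),
                start=int(r.Start) + 1,
                end=int(r.End),
                strand=str(getattr(r, "Strand", "unknown")),
            )
            for r in df.itertuples()
        ]
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    if not genes:
        raise ValueError(f"no gene intervals read from {path}")
    return genes


def call_shared_loci(
    pair: HarmonizedPair,
    result: CfdrResult,
    ccfdr_max: float = 0.01,
    p_max: float = 1e-5,
) -> list[SharedLocus]:
    """Keep SNPs with ccFDR < ccfdr_max and p < p_max in both traits.

    All three thresholds are strict.  The per-trait filter uses the
    genomic-control-corrected p-values when the result carries them
    (correction precedes everything downstream, and corrected p >= raw p,
    so this is the conservative reading).  The returned loci are sorted by
    (chrom, pos).
    """
    if len(result) != len(pair) or not np.array_equal(result.snp_ids, pair.snp_ids):
        raise ValueError("CfdrResult is not aligned to the pair")
    p_a = result.p_a_gc if result.p_a_gc is not None else pair.p_a
    p_b = result.p_b_gc if result.p_b_gc is not None else pair.p_b
    keep = (result.ccfdr < ccfdr_max) & (p_a < p_max) & (p_b < p_max)
    idx = np.flatnonzero(keep)
    order = np.lexsort(
        (pair.pos[idx], _chrom_sort_key(pd.Series(pair.chrom[idx])).to_numpy())
    )
    return [
        SharedLocus(
            snp_id=str(pair.snp_ids[k]),
            chrom=str(pair.chrom[k]),
            pos=int(pair.pos[k]),
            ccfdr=float(result.ccfdr[k]),
            p_a=float(p_a[k]),
            p_b=float(p_b[k]),
        )
        for k in idx[order]
    ]


def average_duplicate_ccfdr(loci: list[SharedLocus]) -> list[SharedLocus]:
    """Collapse loci sharing an rsID to one record with the mean ccFDR.

    SNPs can acquire several ccFDR values (e.g. the same rsID entering the
    analysis more than once); the average is reported.  Duplicates at
    *different* positions are kept separate with a warning — same name,
    different place is a data problem, not a statistic to average.
    Idempotent.
    """
    groups: dict = {}
    for loc in loci:
        groups.setdefault((loc.snp_id, loc.chrom, loc.pos), []).append(loc)

    by_id: dict = {}
    for (snp_id, _, _) in groups:
        by_id.setdefault(snp_id, 0)
        by_id[snp_id] += 1
    for snp_id, n in by_id.items():
        if n > 1:
            warnings.warn(f"rsID {snp_id} occurs at {n} distinct positions; kept separate")

    out = []
    for (snp_id, chrom, pos), members in groups.items():
        first = members[0]
        out.append(
            SharedLocus(
                snp_id=snp_id,
                chrom=chrom,
                pos=pos,
                ccfdr=float(np.mean([m.ccfdr for m in members])),
                p_a=first.p_a,
                p_b=first.p_b,
                closest_genes=list(first.closest_genes),
            )
        )
    return out


def _nearest_genes(chrom: str, pos: int, annotation: list[GeneAnnotation]) -> list[str]:
    here = [g for g in annotation if g.chrom == chrom]
    if not here:
        return ["NA"]
    dists = np.array([g.distance_to(pos) for g in here])
    best = dists.min()
    winners = [g for g, d in zip(here, dists) if d == best]
    winners.sort(key=lambda g: (g.start, g.gene_symbol))
    return [g.gene_symbol for g in winners]


def annotate_nearest_gene(
    loci: list[SharedLocus], annotation: list[GeneAnnotation]
) -> list[SharedLocus]:
    """Assign each locus the containing gene(s), else the closest by distance.

    Distance to an interval is max(start - pos, pos - end, 0); a SNP inside
    one or more genes gets all containing genes (ascending start), and
    exact distance ties return every tied gene.  A locus on a chromosome
    with no annotated gene gets ``["NA"]`` with a warning.
    """
    out = []
    for loc in loci:
        genes = _nearest_genes(loc.chrom, loc.pos, annotation)
        if genes == ["NA"]:
            warnings.warn(f"no annotation on chromosome {loc.chrom} for {loc.snp_id}")
        out.append(
            SharedLocus(
                snp_id=loc.snp_id,
                chrom=loc.chrom,
                pos=loc.pos,
                ccfdr=loc.ccfdr,
                p_a=loc.p_a,
                p_b=loc.p_b,
                closest_genes=genes,
            )
        )
    return out


def unique_gene_set(loci: list[SharedLocus]) -> list[str]:
    """Alphabetically sorted union of all closest-gene assignments."""
    symbols = {g for loc in loci for g in loc.closest_genes if g != "NA"}
    return sorted(symbols)


def manhattan_table(loci: list[SharedLocus]) -> pd.DataFrame:
    """(chrom, pos, -log10 ccFDR) rows, sorted by genomic coordinate."""
    for loc in loci:
        if loc.ccfdr <= 0:
            raise ValueError(f"non-positive ccFDR for {loc.snp_id}")
    df = pd.DataFrame(
        {
            "chrom": [l.chrom for l in loci],
            "pos": [l.pos for l in loci],
            "minus_log10_ccfdr": [-np.log10(l.ccfdr) for l in loci],
        }
    )
    order = np.lexsort((df["pos"].to_numpy(), _chrom_sort_key(df["chrom"]).to_numpy()))
    return df.iloc[order].reset_index(drop=True)


@dataclass
class OverlapSummary:
    """Discovery/replication agreement of two called locus lists."""

    shared_ids: list
    n_discovery: int
    n_replication: int
    n_shared: int
    jaccard: float


def replication_overlap(
    discovery: list[SharedLocus], replication: list[SharedLocus]
) -> OverlapSummary:
    """rsID intersection, counts and Jaccard index of two locus lists."""
    d = {l.snp_id for l in discovery}
    r = {l.snp_id for l in replication}
    union = d | r
    inter = d & r
    return OverlapSummary(
        shared_ids=sorted(inter),
        n_discovery=len(d),
        n_replication=len(r),
        n_shared=len(inter),
        jaccard=len(inter) / len(union) if union else 1.0,
    )


def clump_loci(loci: list[SharedLocus], window_bp: int) -> list[SharedLocus]:
    """Greedy best-ccFDR-first clumping within a base-pair window (optional).

    Off by default in the pipeline; provided for users who want one
    representative SNP per region.
    """
    remaining = sorted(loci, key=lambda l: l.ccfdr)
    kept: list[SharedLocus] = []
    for loc in remaining:
        if any(k.chrom == loc.chrom and abs(k.pos - loc.pos) <= window_bp for k in kept):
            continue
        kept.append(loc)
    kept.sort(key=lambda l: (_chrom_sort_key(pd.Series([l.chrom])).iloc[0], l.pos))
    return kept


def loci_table(loci: list[SharedLocus]) -> pd.DataFrame:
    """Serialize called loci (comma+space joined gene symbols)."""
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(loci) + 1),
            "snp_id": [l.snp_id for l in loci],
            "chrom": [l.chrom for l in loci],
            "pos": [l.pos for l in loci],
            "p_a": [l.p_a for l in loci],
            "p_b": [l.p_b for l in loci],
            "ccfdr": [l.ccfdr for l in loci],
            "closest_genes": [", ".join(l.closest_genes) for l in loci],
        }
    )
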