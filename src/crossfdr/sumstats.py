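"""Reading, validating, filtering and harmonizing GWAS summary statistics.

Summary statistics are per-SNP association records released without
individual-level genotypes.  This module turns delimited text files into
validated :class:`SumstatsTable` objects, applies the standard marker-level
quality-control filters (minor allele frequency, Hardy-Weinberg equilibrium,
call rate) when those columns are present, collapses duplicate rsIDs, and
intersects two tables into a :class:`HarmonizedPair` — the aligned p-value
vectors every cross-trait computation downstream consumes.

Only p-values are used by the pleiotropy statistics, so no strand or
effect-allele alignment is performed here (and none is needed): two tables
are harmonized purely by rsID and genomic coordinate.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of a summary-statistics table
CANONICAL_COLUMNS = ["snp_id", "chrom", "pos", "pvalue", "maf", "hwe_p", "call_rate"]
MANDATORY = ["snp_id", "chrom", "pos", "pvalue"]

#: default header names for the mandatory columns, by semantic name
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "pvalue": "P",
}


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric-aware chromosome ordering: 1..22 before X, Y, MT."""
    num = pd.to_numeric(chrom, errors="coerce")
    return num.fillna(1000).astype(float)


@dataclass
class SumstatsTable:
    """One trait's summary statistics.

    ``df`` holds the canonical columns ``snp_id, chrom, pos, pvalue`` plus
    any of ``maf, hwe_p, call_rate`` that the source provided.  ``meta``
    records ingest/QC bookkeeping (rows dropped per reason).
    """

    trait_name: str
    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pvalues(self) -> np.ndarray:
        return self.df["pvalue"].to_numpy(float)


@dataclass
class HarmonizedPair:
    """Two traits aligned on their shared SNPs, sorted by (chrom, pos).

    ``p_a``/``p_b`` are the per-SNP p-value vectors for trait A and B; the
    coordinate vectors are shared (coordinate conflicts between sources are
    excluded and listed in ``conflicts``).
    """

    trait_a: str
    trait_b: str
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    p_a: np.ndarray
    p_b: np.ndarray
    conflicts: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.snp_ids)

    def swapped(self) -> "HarmonizedPair":
        """The same pair with the roles of trait A and B interchanged."""
        return HarmonizedPair(
            trait_a=self.trait_b,
            trait_b=self.trait_a,
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            p_a=self.p_b,
            p_b=self.p_a,
            conflicts=self.conflicts,
        )


def read_sumstats(
    path,
    column_map: dict | None = None,
    delimiter: str = "\t",
    trait_name: str | None = None,
) -> SumstatsTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path
        Delimited text file (optionally gzip-compressed) with a header row.
    column_map
        Mapping semantic name -> source column name.  Defaults cover the
        common ``SNP/CHR/BP/P`` dialect; optional fields are picked up when
        mapped (``maf``, ``hwe_p``, ``call_rate``).
    delimiter
        Field separator; ``None`` means any whitespace.

    Rows failing validation (non-numeric or out-of-range p-value, bad
    position, out-of-range MAF) are dropped and tallied in ``meta``.
    Exact zero p-values — which occur in downloaded summary statistics when
    a tool underflows — are clamped to 0.1x the smallest positive p in the
    table so that -log10 transforms stay finite.

    Raises
    ------
    ValueError
        If a mandatory mapped column is missing from the header.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep=delimiter if delimiter else r"\s+", dtype=str)
    for sem in MANDATORY:
        if cmap[sem] not in raw.columns:
            raise ValueError(
                f"mandatory column {sem!r} (source name {cmap[sem]!r}) "
                f"not found in header {list(raw.columns)}"
            )

    present = {sem: src for sem, src in cmap.items() if src in raw.columns}
    df = raw[[present[s] for s in CANONICAL_COLUMNS if s in present]].copy()
    df.columns = [s for s in CANONICAL_COLUMNS if s in present]

    meta: dict = {"n_input": len(df)}
    bad = pd.Series(False, index=df.index)

    df["pvalue"] = pd.to_numeric(df["pvalue"], errors="coerce")
    bad_p = df["pvalue"].isna() | (df["pvalue"] < 0) | (df["pvalue"] > 1)
    meta["n_bad_pvalue"] = int(bad_p.sum())
    bad |= bad_p

    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    bad_pos = df["pos"].isna() | (df["pos"] < 1) | (df["pos"] % 1 != 0)
    meta["n_bad_pos"] = int(bad_pos.sum())
    bad |= bad_pos

    bad_id = df["snp_id"].isna() | (df["snp_id"].str.len() == 0)
    meta["n_bad_snp_id"] = int(bad_id.sum())
    bad |= bad_id

    for col, lo, hi in [("maf", 0.0, 0.5), ("hwe_p", 0.0, 1.0), ("call_rate", 0.0, 1.0)]:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            # missing is allowed; a present value must be in range
            bad_col = df[col].notna() & ((df[col] <= lo) | (df[col] > hi))
            meta[f"n_bad_{col}"] = int(bad_col.sum())
            bad |= bad_col

    df = df.loc[~bad].reset_index(drop=True)
    meta["n_dropped"] = int(bad.sum())

    # clamp p == 0 to 0.1x the smallest observed positive p
    zero = df["pvalue"] == 0.0
    if zero.any():
        positive = df.loc[~zero, "pvalue"]
        floor = float(positive.min()) * 0.1 if len(positive) else 1e-300
        df.loc[zero, "pvalue"] = floor
        meta["n_zero_p_clamped"] = int(zero.sum())
        logger.warning("clamped %d zero p-values to %.3g", int(zero.sum()), floor)

    df["pos"] = df["pos"].astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)

    name = trait_name or Path(str(path)).stem
    if meta["n_dropped"]:
        logger.info("%s: dropped %d/%d rows at ingest", name, meta["n_dropped"], meta["n_input"])
    return SumstatsTable(trait_name=name, df=df, meta=meta)


def write_sumstats(table: SumstatsTable, path) -> None:
    """Write the canonical TSV dialect (round-trips through read_sumstats)."""
    cols = [c for c in CANONICAL_COLUMNS if c in table.df.columns]
    out = table.df[cols].rename(
        columns={"snp_id": "SNP", "chrom": "CHR", "pos": "BP", "pvalue": "P"}
    )
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


def apply_qc(
    table: SumstatsTable,
    maf_min: float = 0.01,
    hwe_min: float = 1e-6,
    call_rate_min: float = 0.95,
) -> tuple[SumstatsTable, dict]:
    """Marker-level QC: drop SNPs with MAF < 1%, HWE p < 1e-6 or call rate < 95%.

    A record lacking a QC field passes that filter — public summary
    statistics frequently omit them because the filters were applied
    upstream at genotype level.  Returns the filtered table and a dict of
    counts removed per criterion (a row failing several is counted in each).
    """
    for name, thr in [("maf_min", maf_min), ("hwe_min", hwe_min), ("call_rate_min", call_rate_min)]:
        if not 0 <= thr < 1:
            raise ValueError(f"{name} must be in [0, 1), got {thr}")
    df = table.df
    removed = {}
    keep = pd.Series(True, index=df.index)
    for col, thr in [("maf", maf_min), ("hwe_p", hwe_min), ("call_rate", call_rate_min)]:
        if col in df.columns:
            fail = df[col].notna() & (df[col] < thr)
        else:
            fail = pd.Series(False, index=df.index)
        removed[col] = int(fail.sum())
        keep &= ~fail
    out = SumstatsTable(
        trait_name=table.trait_name,
        df=df.loc[keep].reset_index(drop=True),
        meta={**table.meta, "qc_removed": removed},
    )
    return out, removed


def dedupe_mean_p(table: SumstatsTable) -> SumstatsTable:
    """Collapse duplicated rsIDs to a single record with the mean p-value.

    First-seen coordinates are kept.  Duplicates that disagree on
    chromosome are unresolvable and all copies are dropped (reported in
    ``meta['dedupe_conflicts']``).  Idempotent.
    """
    df = table.df
    if df["snp_id"].is_unique:
        return SumstatsTable(table.trait_name, df.copy(), dict(table.meta))

    n_chrom = df.groupby("snp_id")["chrom"].nunique()
    conflicted = set(n_chrom.index[n_chrom > 1])
    if conflicted:
        logger.warning("dropping %d rsIDs duplicated across chromosomes", len(conflicted))
    df = df[~df["snp_id"].isin(conflicted)]

    agg = {c: "first" for c in df.columns if c not in ("snp_id", "pvalue")}
    agg["pvalue"] = "mean"
    out = df.groupby("snp_id", sort=False, as_index=False).agg(agg)
    out = out[[c for c in table.df.columns]]
    meta = {**table.meta, "dedupe_conflicts": sorted(conflicted),
            "n_deduped": len(table.df) - len(out)}
    return SumstatsTable(table.trait_name, out.reset_index(drop=True), meta)


def harmonize_pair(a: SumstatsTable, b: SumstatsTable) -> HarmonizedPair:
    """Intersect two deduplicated tables by rsID into aligned p-value vectors.

    The result is sorted by (chrom, pos).  SNPs whose coordinates disagree
    between the two sources are excluded and returned in ``conflicts``.

    Raises
    ------
    ValueError
        If either table still contains duplicate rsIDs, or if the
        intersection is empty.
    """
    for t in (a, b):
        if not t.df["snp_id"].is_unique:
            raise ValueError(f"table {t.trait_name!r} has duplicate rsIDs; dedupe first")

    merged = a.df.merge(b.df, on="snp_id", suffixes=("_a", "_b"), how="inner")
    if merged.empty:
        raise ValueError(
            f"no shared rsIDs between {a.trait_name!r} and {b.trait_name!r}"
        )
    conflict = (merged["chrom_a"] != merged["chrom_b"]) | (merged["pos_a"] != merged["pos_b"])
    conflicts = merged.loc[
        conflict, ["snp_id", "chrom_a", "pos_a", "chrom_b", "pos_b"]
    ].reset_index(drop=True)
    if len(conflicts):
        logger.warning("excluding %d rsIDs with conflicting coordinates", len(conflicts))
    merged = merged.loc[~conflict]
    if merged.empty:
        raise ValueError("all shared rsIDs had conflicting coordinates")

    order = np.lexsort((merged["pos_a"].to_numpy(), _chrom_sort_key(merged["chrom_a"]).to_numpy()))
    merged = merged.iloc[order]
    return HarmonizedPair(
        trait_a=a.trait_name,
        trait_b=b.trait_name,
        snp_ids=merged["snp_id"].to_numpy(),
        chrom=merged["chrom_a"].to_numpy(),
        pos=merged["pos_a"].to_numpy(np.int64),
        p_a=merged["pvalue_a"].to_numpy(float),
        p_b=merged["pvalue_b"].to_numpy(float),
        conflicts=conflicts if len(conflicts) else None,
    )


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str):
    return resources.files("crossfdr.data").joinpath(name)


def load_table1_fixture():
    """The 49 published shared AD/glaucoma loci (chr11 p-arm cluster).

    Returns a list of :class:`crossfdr.loci.SharedLocus` with rsID,
    coordinates, the published closest-gene assignment, and ccFDR.
    """
    from .loci import SharedLocus  # local import to avoid a cycle

    df = pd.read_csv(_data_path("table1_shared_loci.tsv"), sep="\t", dtype=str)
    expected_cols = ["rank", "rsid", "chrom", "pos", "closest_genes", "ccfdr"]
    if list(df.columns) != expected_cols:
        raise ValueError(f"fixture columns {list(df.columns)} != {expected_cols}")
    if len(df) != 49:
        raise ValueError(f"fixture row count {len(df)} != 49")
    loci = []
    for _, row in df.iterrows():
        loci.append(
            SharedLocus(
                snp_id=row["rsid"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ccfdr=float(row["ccfdr"]),
                closest_genes=[g.strip() for g in row["closest_genes"].split(",")],
            )
        )
    return loci


def load_table2_fixture() -> pd.DataFrame:
    """Static table of the 11 shared genes and their published functions."""
    return pd.read_csv(_data_path("table2_gene_functions.tsv"), sep="\t")


def load_toy_genes():
    """Small packaged gene-annotation fixture (BED) for annotation tests."""
    from .loci import read_gene_annotations

    return read_gene_annotations(str(_data_path("toy_genes.bed")), fmt="bed")
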