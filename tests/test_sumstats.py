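"""Ingest, validation, QC filters, deduplication and harmonization."""

import numpy as np
import pandas as pd
import pytest

from crossfdr import (
    SumstatsTable,
    apply_qc,
    dedupe_mean_p,
    harmonize_pair,
    load_table1_fixture,
    load_table2_fixture,
    read_sumstats,
    write_sumstats,
)


def _write(tmp_path, text, name="ss.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


WELL_FORMED = (
    "SNP\tCHR\tBP\tP\n"
    "rs1\t1\t100\t0.5\n"
    "rs2\t1\t200\t0.01\n"
    "rs3\t2\t50\t0.2\n"
    "rs4\t2\t150\t1e-6\n"
    "rs5\t3\t10\t0.9\n"
)


class TestReadSumstats:
    def test_well_formed_five_rows(self, tmp_path):
        t = read_sumstats(_write(tmp_path, WELL_FORMED))
        assert len(t) == 5
        assert list(t.df["snp_id"]) == ["rs1", "rs2", "rs3", "rs4", "rs5"]

    def test_out_of_range_pvalue_row_rejected(self, tmp_path):
        text = WELL_FORMED + "rs6\t3\t20\t1.2\n"
        t = read_sumstats(_write(tmp_path, text))
        assert len(t) == 5
        assert t.meta["n_bad_pvalue"] == 1

    def test_unparsable_pvalue_row_rejected(self, tmp_path):
        text = WELL_FORMED + "rs6\t3\t20\tnot_a_p\n"
        t = read_sumstats(_write(tmp_path, text))
        assert len(t) == 5

    def test_column_map_invariance(self, tmp_path):
        alt = WELL_FORMED.replace("SNP\tCHR\tBP\tP", "rsid\tchromosome\tposition\tpval")
        t1 = read_sumstats(_write(tmp_path, WELL_FORMED, "a.tsv"))
        t2 = read_sumstats(
            _write(tmp_path, alt, "b.tsv"),
            column_map={"snp_id": "rsid", "chrom": "chromosome", "pos": "position", "pvalue": "pval"},
        )
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        text = "SNP\tCHR\tBP\n" + "rs1\t1\t100\n"
        with pytest.raises(ValueError, match="pvalue"):
            read_sumstats(_write(tmp_path, text))

    def test_zero_pvalue_clamped_to_tenth_of_min_positive(self, tmp_path):
        text = "SNP\tCHR\tBP\tP\nrs1\t1\t1\t0\nrs2\t1\t2\t1e-10\nrs3\t1\t3\t0.5\n"
        t = read_sumstats(_write(tmp_path, text))
        assert t.df.loc[t.df["snp_id"] == "rs1", "pvalue"].item() == pytest.approx(1e-11)
        assert t.meta["n_zero_p_clamped"] == 1

    def test_round_trip_byte_identical(self, tmp_path, small_table):
        f1, f2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        write_sumstats(small_table, f1)
        t = read_sumstats(f1)
        write_sumstats(t, f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_gzip_input(self, tmp_path):
        import gzip

        p = tmp_path / "ss.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(WELL_FORMED)
        assert len(read_sumstats(p)) == 5


class TestApplyQc:
    def _with_qc(self, maf=None, hwe=None, cr=None):
        df = pd.DataFrame(
            {
                "snp_id": ["rs1"],
                "chrom": ["1"],
                "pos": [100],
                "pvalue": [0.5],
            }
        )
        if maf is not None:
            df["maf"] = maf
        if hwe is not None:
            df["hwe_p"] = hwe
        if cr is not None:
            df["call_rate"] = cr
        return SumstatsTable("t", df)

    def test_low_maf_removed(self):
        out, removed = apply_qc(self._with_qc(maf=0.005))
        assert len(out) == 0 and removed["maf"] == 1

    def test_hwe_violation_removed_missing_retained(self):
        t = self._with_qc(hwe=1e-7)
        t.df = pd.concat(
            [t.df, t.df.assign(snp_id="rs2", hwe_p=np.nan)], ignore_index=True
        )
        out, removed = apply_qc(t)
        assert list(out.df["snp_id"]) == ["rs2"]
        assert removed["hwe_p"] == 1

    def test_pvalue_only_table_unchanged(self, small_table):
        out, removed = apply_qc(small_table)
        pd.testing.assert_frame_equal(out.df, small_table.df)
        assert sum(removed.values()) == 0

    def test_vacuous_thresholds_are_identity(self):
        t = self._with_qc(maf=0.004, hwe=1e-8, cr=0.5)
        out, _ = apply_qc(t, maf_min=0.0, hwe_min=0.0, call_rate_min=0.0)
        assert len(out) == 1

    def test_never_increases_count(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(50)],
                "chrom": "1",
                "pos": np.arange(1, 51),
                "pvalue": rng.uniform(size=50),
                "maf": rng.uniform(0, 0.5, size=50),
            }
        )
        t = SumstatsTable("t", df)
        for thr in (0.0, 0.01, 0.1, 0.5):
            out, _ = apply_qc(t, maf_min=thr)
            assert len(out) <= len(t)

    def test_bad_threshold_rejected(self, small_table):
        with pytest.raises(ValueError):
            apply_qc(small_table, maf_min=1.5)


class TestDedupeMeanP:
    def _dup_table(self, pvals, chroms=None):
        n = len(pvals)
        return SumstatsTable(
            "t",
            pd.DataFrame(
                {
                    "snp_id": ["rsX"] * n,
                    "chrom": chroms or ["1"] * n,
                    "pos": [100] * n,
                    "pvalue": pvals,
                }
            ),
        )

    def test_mean_of_two(self):
        out = dedupe_mean_p(self._dup_table([0.02, 0.04]))
        assert len(out) == 1
        assert out.df["pvalue"].item() == pytest.approx(0.03)

    def test_mean_of_three(self):
        out = dedupe_mean_p(self._dup_table([0.1, 0.2, 0.6]))
        assert out.df["pvalue"].item() == pytest.approx(0.3)

    def test_no_duplicates_identity(self, small_table):
        out = dedupe_mean_p(small_table)
        pd.testing.assert_frame_equal(out.df, small_table.df)

    def test_idempotent(self):
        once = dedupe_mean_p(self._dup_table([0.1, 0.2, 0.6]))
        twice = dedupe_mean_p(once)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_conflicting_chrom_all_dropped(self):
        out = dedupe_mean_p(self._dup_table([0.1, 0.2], chroms=["1", "2"]))
        assert len(out) == 0
        assert out.meta["dedupe_conflicts"] == ["rsX"]

    def test_first_seen_coordinates_kept(self):
        t = SumstatsTable(
            "t",
            pd.DataFrame(
                {
                    "snp_id": ["rsX", "rsX"],
                    "chrom": ["1", "1"],
                    "pos": [100, 999],
                    "pvalue": [0.1, 0.3],
                }
            ),
        )
        out = dedupe_mean_p(t)
        assert out.df["pos"].item() == 100


class TestHarmonizePair:
    def _table(self, ids, chroms, pos, pvals, name="t"):
        return SumstatsTable(
            name,
            pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": pos, "pvalue": pvals}),
        )

    def test_intersection_of_three(self, small_table):
        other = self._table(
            ["rs2", "rs4", "rs5", "rs9", "rs10"],
            ["1", "2", "3", "4", "4"],
            [200, 150, 10, 5, 6],
            [0.3, 0.4, 0.5, 0.6, 0.7],
            "u",
        )
        pair = harmonize_pair(small_table, other)
        assert len(pair) == 3
        assert set(pair.snp_ids) == {"rs2", "rs4", "rs5"}

    def test_positional_conflict_excluded_and_reported(self, small_table):
        other = self._table(["rs2", "rs4"], ["1", "2"], [200, 151], [0.3, 0.4], "u")
        pair = harmonize_pair(small_table, other)
        assert set(pair.snp_ids) == {"rs2"}
        assert list(pair.conflicts["snp_id"]) == ["rs4"]

    def test_self_harmonization_identity(self, small_table):
        pair = harmonize_pair(small_table, small_table)
        np.testing.assert_array_equal(pair.p_a, pair.p_b)
        assert len(pair) == 5

    def test_symmetric_in_content(self, small_table):
        other = self._table(["rs2", "rs4"], ["1", "2"], [200, 150], [0.3, 0.4], "u")
        ab = harmonize_pair(small_table, other)
        ba = harmonize_pair(other, small_table)
        assert set(ab.snp_ids) == set(ba.snp_ids)
        np.testing.assert_array_equal(ab.p_a, ba.p_b)
        np.testing.assert_array_equal(ab.p_b, ba.p_a)

    def test_sorted_by_chrom_pos(self, small_table):
        pair = harmonize_pair(small_table, small_table)
        order = np.lexsort((pair.pos, [int(c) for c in pair.chrom]))
        np.testing.assert_array_equal(order, np.arange(len(pair)))

    def test_empty_intersection_is_hard_error(self, small_table):
        other = self._table(["rs99"], ["1"], [1], [0.5], "u")
        with pytest.raises(ValueError, match="no shared"):
            harmonize_pair(small_table, other)

    def test_duplicates_rejected(self, small_table):
        dup = self._table(["rs1", "rs1"], ["1", "1"], [100, 100], [0.1, 0.2], "u")
        with pytest.raises(ValueError, match="duplicate"):
            harmonize_pair(small_table, dup)


class TestFixtures:
    def test_published_locus_table_first_row(self):
        loci = load_table1_fixture()
        first = loci[0]
        assert (first.snp_id, first.chrom, first.pos) == ("rs2856661", "11", 47374998)
        assert first.closest_genes == ["SPI1", "MYBPC3"]
        assert first.ccfdr == pytest.approx(2.59e-5)

    def test_published_locus_table_row_29(self):
        loc = load_table1_fixture()[28]
        assert (loc.snp_id, loc.pos, loc.closest_genes) == ("rs1317164", 47419757, ["MTCH2"])
        assert loc.ccfdr == pytest.approx(9.46e-6)

    def test_published_locus_table_has_49_rows(self):
        assert len(load_table1_fixture()) == 49

    def test_gene_function_table_has_11_genes(self):
        df = load_table2_fixture()
        assert len(df) == 11
        assert "MTCH2" in set(df["gene"])
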