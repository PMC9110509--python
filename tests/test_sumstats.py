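import gzip

import numpy as np
import pandas as pd
import pytest

from pleiocfdr.sumstats import (
    CHI2_MEDIAN_1DF,
    MergedPair,
    SumstatsTable,
    genomic_control,
    harmonize_and_merge,
    load_column_map,
    read_sumstats,
    write_sumstats,
)
from tests.conftest import make_sumstats

HEADER = "snp_id\tchrom\tpos\teffect_allele\tother_allele\tbeta\tse\tp\tmaf\tn"


def write_file(tmp_path, rows, header=HEADER, name="ss.tsv"):
    path = tmp_path / name
    path.write_text("\n".join([header] + rows) + ("\n" if rows else "\n"))
    return path


class TestReadSumstats:
    def test_header_only_file_gives_empty_valid_table(self, tmp_path):
        table = read_sumstats(write_file(tmp_path, []))
        assert len(table) == 0

    def test_z_derived_from_beta_se(self, tmp_path):
        rows = [f"rs{i}\t1\t{i * 100}\tA\tG\t0.1\t0.05\t0.5\t0.2\t1000" for i in (1, 2, 3)]
        table = read_sumstats(write_file(tmp_path, rows))
        assert np.allclose(table.df["z"], 2.0)

    def test_p_derived_from_z_when_missing(self, tmp_path):
        path = write_file(tmp_path, ["rs1\t1\t100\t1.959964", "rs2\t1\t200\t0.0"],
                          header="snp_id\tchrom\tpos\tz")
        table = read_sumstats(path)
        assert table.df["p"].iloc[0] == pytest.approx(0.05, rel=1e-5)
        assert table.df["p"].iloc[1] == 1.0

    def test_partially_missing_p_filled_from_z(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("snp_id\tchrom\tpos\tz\tp\nrs1\t1\t100\t1.959964\t\nrs2\t1\t200\t0.5\t0.6\n")
        table = read_sumstats(path)
        assert table.df["p"].iloc[0] == pytest.approx(0.05, rel=1e-5)
        assert table.df["p"].iloc[1] == 0.6

    def test_rows_sorted_by_chrom_pos_matches_independent_sort(self, tmp_path, rng):
        chroms = rng.choice(["1", "2", "10", "X"], size=10)
        positions = rng.integers(1, 10**6, size=10)
        rows = [
            f"rs{i}\t{c}\t{p}\tA\tG\t0.1\t0.1\t0.5\t0.2\t10"
            for i, (c, p) in enumerate(zip(chroms, positions))
        ]
        table = read_sumstats(write_file(tmp_path, rows))
        chrom_rank = {"1": 1, "2": 2, "10": 10, "X": 23}
        expected = sorted(
            zip(chroms.tolist(), positions.tolist()), key=lambda t: (chrom_rank[t[0]], t[1])
        )
        got = list(zip(table.df["chrom"], table.df["pos"]))
        assert got == [(c, p) for c, p in expected]

    def test_zero_p_floored_with_warning(self, tmp_path, caplog):
        path = write_file(tmp_path, ["rs1\t1\t100\tA\tG\t1.0\t0.1\t0\t0.2\t10",
                                     "rs2\t1\t200\tA\tG\t0.1\t0.1\t0.5\t0.2\t10"])
        with caplog.at_level("WARNING", logger="pleiocfdr"):
            table = read_sumstats(path)
        assert table.df["p"].iloc[0] == 1e-300
        assert any("floored" in r.message for r in caplog.records)

    @pytest.mark.parametrize(
        "row,msg",
        [
            ("rs1\t1\t100\tA\tG\tnot_a_number\t0.1\t0.5\t0.2\t10", "line 2"),
            ("rs1\t1\t100\tA\tG\t0.1\t0.1\t1.5\t0.2\t10", "line 2"),
            ("rs1\t1\t100\tA\tG\t0.1\t0.1\t-0.5\t0.2\t10", "line 2"),
            ("rs1\t1\t100\tA\tA\t0.1\t0.1\t0.5\t0.2\t10", "line 2"),
        ],
    )
    def test_malformed_rows_error_with_line_number(self, tmp_path, row, msg):
        with pytest.raises(ValueError, match=msg):
            read_sumstats(write_file(tmp_path, [row]))

    def test_duplicate_snp_id_error_lists_duplicates(self, tmp_path):
        rows = [f"rs1\t1\t{p}\tA\tG\t0.1\t0.1\t0.5\t0.2\t10" for p in (100, 200)]
        with pytest.raises(ValueError, match="rs1"):
            read_sumstats(write_file(tmp_path, rows))

    def test_column_map_and_gzip_input(self, tmp_path):
        content = "marker\tchr\tbp\tpval\tzscore\nrs1\t2\t500\t0.01\t2.5\n"
        path = tmp_path / "ss.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(content)
        cfg = tmp_path / "cols.yaml"
        cfg.write_text("snp_id: marker\nchrom: chr\npos: bp\np: pval\nz: zscore\n")
        table = read_sumstats(path, load_column_map(cfg))
        assert table.df.loc[0, "p"] == 0.01 and table.df.loc[0, "z"] == 2.5

    def test_roundtrip_write_read_identical(self, tmp_path, rng):
        z = rng.standard_normal(20)
        table = make_sumstats(
            [f"rs{i}" for i in range(20)], ["1"] * 20, np.arange(1, 21) * 10, z=z,
            maf=rng.uniform(0.05, 0.5, 20),
        )
        path = tmp_path / "out.tsv"
        write_sumstats(table, path)
        back = read_sumstats(path)
        pd.testing.assert_frame_equal(back.df[table.df.columns], table.df)


class TestGenomicControl:
    def null_calibrated(self):
        c = np.sqrt(CHI2_MEDIAN_1DF)
        return make_sumstats(["a", "b", "c", "d"], [1] * 4, [1, 2, 3, 4],
                             z=[0.1, c, -c, 3.0])

    def test_null_calibrated_z_gives_lambda_one_unchanged(self):
        table = self.null_calibrated()
        out = genomic_control(table)
        assert out.gc_lambda == pytest.approx(1.0, abs=1e-12)
        pd.testing.assert_frame_equal(out.df, table.df)

    def test_inflated_by_sqrt2_gives_lambda_two_and_restores_z(self):
        base = self.null_calibrated()
        inflated = make_sumstats(["a", "b", "c", "d"], [1] * 4, [1, 2, 3, 4],
                                 z=base.df["z"].to_numpy() * np.sqrt(2))
        out = genomic_control(inflated)
        assert out.gc_lambda == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(out.df["z"], base.df["z"], atol=1e-12)

    def test_single_record_is_an_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            genomic_control(make_sumstats(["a"], [1], [1], z=[1.0]))

    def test_no_deflation_when_lambda_below_one(self):
        table = make_sumstats(list("abcd"), [1] * 4, [1, 2, 3, 4], z=[0.01, 0.02, -0.01, 0.03])
        out = genomic_control(table)
        assert out.gc_lambda < 1
        pd.testing.assert_frame_equal(out.df, table.df)

    def test_idempotent(self, rng):
        z = rng.standard_normal(500) * 1.7
        table = make_sumstats([f"s{i}" for i in range(500)], [1] * 500,
                              np.arange(1, 501), z=z)
        once = genomic_control(table)
        twice = genomic_control(once)
        assert twice.gc_lambda == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(twice.df["z"], once.df["z"], atol=1e-12)


class TestHarmonizeAndMerge:
    def alleles(self, *pairs):
        return list(pairs)

    def test_identical_panels_identity(self):
        t = make_sumstats(list("abcde"), [1] * 5, range(1, 6), z=[1, -2, 0.5, 3, -1],
                          alleles=self.alleles(*[("A", "G")] * 5))
        merged = harmonize_and_merge(t, t)
        assert len(merged) == 5
        np.testing.assert_array_equal(merged.df["z2"], merged.df["z1"])

    def test_swapped_alleles_flip_z2_sign(self):
        t1 = make_sumstats(["a"], [1], [1], z=[2.0], alleles=[("A", "G")])
        t2 = make_sumstats(["a"], [1], [1], z=[1.5], alleles=[("G", "A")])
        merged = harmonize_and_merge(t1, t2)
        assert merged.df.loc[0, "z2"] == -1.5

    def test_complementary_strand_resolved(self):
        t1 = make_sumstats(["a"], [1], [1], z=[2.0], alleles=[("A", "G")])
        t2 = make_sumstats(["a"], [1], [1], z=[1.5], alleles=[("T", "C")])  # complement, same order
        merged = harmonize_and_merge(t1, t2)
        assert merged.df.loc[0, "z2"] == 1.5
        t2s = make_sumstats(["a"], [1], [1], z=[1.5], alleles=[("C", "T")])  # complement, swapped
        assert harmonize_and_merge(t1, t2s).df.loc[0, "z2"] == -1.5

    def test_strand_ambiguous_snp_dropped_and_counted(self):
        # hand enumeration: of the three SNPs only "b" (A/T) is self-complementary
        t = make_sumstats(list("abc"), [1] * 3, range(1, 4), z=[1, 1, 1],
                          alleles=self.alleles(("A", "G"), ("A", "T"), ("C", "A")))
        merged = harmonize_and_merge(t, t)
        assert sorted(merged.df["snp_id"]) == ["a", "c"]
        assert merged.n_dropped_ambiguous == 1

    def test_irreconcilable_alleles_dropped_and_counted(self):
        t1 = make_sumstats(["a", "b"], [1, 1], [1, 2], z=[1, 1],
                           alleles=self.alleles(("A", "G"), ("A", "C")))
        t2 = make_sumstats(["a", "b"], [1, 1], [1, 2], z=[1, 1],
                           alleles=self.alleles(("A", "G"), ("A", "G")))
        merged = harmonize_and_merge(t1, t2)
        assert merged.df["snp_id"].tolist() == ["a"]
        assert merged.n_dropped_mismatch == 1

    def test_empty_intersection_is_an_error(self):
        t1 = make_sumstats(["a"], [1], [1], z=[1.0])
        t2 = make_sumstats(["b"], [1], [1], z=[1.0])
        with pytest.raises(ValueError, match="empty"):
            harmonize_and_merge(t1, t2)

    def test_allele_swapped_copy_gives_z2_equal_minus_z1(self, rng):
        m = 50
        z = rng.standard_normal(m)
        alleles = [("A", "G"), ("C", "A"), ("G", "T"), ("T", "C")] * 13
        t1 = make_sumstats([f"s{i}" for i in range(m)], [1] * m, range(1, m + 1),
                           z=z, alleles=alleles[:m])
        swapped = [(b, a) for a, b in alleles[:m]]
        t2 = make_sumstats([f"s{i}" for i in range(m)], [1] * m, range(1, m + 1),
                           z=z, alleles=swapped)
        merged = harmonize_and_merge(t1, t2)
        assert len(merged) == m
        np.testing.assert_allclose(merged.df["z2"], -merged.df["z1"])

    def test_output_subset_of_both_inputs(self, rng):
        ids1 = [f"s{i}" for i in rng.choice(100, size=40, replace=False)]
        ids2 = [f"s{i}" for i in rng.choice(100, size=40, replace=False)]
        t1 = make_sumstats(ids1, [1] * 40, range(1, 41), z=rng.standard_normal(40))
        t2 = make_sumstats(ids2, [1] * 40, range(1, 41), z=rng.standard_normal(40))
        merged = harmonize_and_merge(t1, t2)
        assert len(merged) <= min(len(t1), len(t2))
        assert set(merged.df["snp_id"]) <= set(ids1) & set(ids2)

    def test_swapped_slots_exchanges_traits(self):
        t1 = make_sumstats(["a"], [1], [1], z=[2.0], trait="bmd")
        t2 = make_sumstats(["a"], [1], [1], z=[1.0], trait="bw")
        sw = harmonize_and_merge(t1, t2).swapped()
        assert sw.trait1_label == "bw"
        assert sw.df.loc[0, "z1"] == 1.0
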