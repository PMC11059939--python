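"""Summary-statistic parsing, instrument selection, clumping, harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from targetmr.sumstats import (LDMatrix, cis_window, clump, harmonize,
                               read_sumstats, select_instruments,
                               write_sumstats)


def _write(tmp_path, df, name="ss.tsv"):
    path = tmp_path / name
    df.to_csv(path, sep="\t", index=False)
    return path


VALID = pd.DataFrame({
    "snp": ["rs1", "rs2", "rs3"], "chr": ["1", "1", "2"],
    "pos": [100, 200, 300], "a1": ["A", "C", "T"], "a2": ["G", "T", "C"],
    "eaf": [0.2, 0.4, 0.25], "beta": [0.05, -0.02, 0.1],
    "se": [0.01, 0.01, 0.02],
    "p": [5.733e-7, 0.0455, 5.733e-7], "n": [5000, 5000, 5000]})


class TestReadSumstats:
    def test_identity_parse(self, tmp_path):
        table = read_sumstats(_write(tmp_path, VALID), "quantitative")
        assert len(table) == 3 and table.n_dropped == 0

    def test_header_driven_parsing_ignores_column_order(self, tmp_path):
        shuffled = VALID[["p", "beta", "snp", "se", "a2", "a1", "chr", "pos",
                          "n", "eaf"]]
        t1 = read_sumstats(_write(tmp_path, VALID, "a.tsv"), "quantitative")
        t2 = read_sumstats(_write(tmp_path, shuffled, "b.tsv"), "quantitative")
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_missing_se_column_is_hard_error(self, tmp_path):
        path = _write(tmp_path, VALID.drop(columns=["se"]))
        with pytest.raises(ValueError, match="missing column: se"):
            read_sumstats(path, "quantitative")

    def test_dialect_maps_foreign_headers(self, tmp_path):
        renamed = VALID.rename(columns={"snp": "SNP", "a1": "A1", "a2": "A2",
                                        "beta": "b", "p": "pval"})
        dialect = {"snp": "SNP", "a1": "A1", "a2": "A2", "beta": "b",
                   "p": "pval"}
        table = read_sumstats(_write(tmp_path, renamed), "quantitative",
                              dialect=dialect)
        assert table.snp_ids == ["rs1", "rs2", "rs3"]

    @pytest.mark.parametrize("bad,reason", [
        ({"se": [0.01, -0.01, 0.02]}, "nonpositive-se"),
        ({"eaf": [0.2, 1.4, 0.25]}, "eaf-out-of-range"),
        ({"a2": ["G", "C", "C"]}, "identical-alleles"),
        ({"p": [5.733e-7, 0.5, 5.733e-7]}, "pval-inconsistent"),
        ({"beta": [0.05, "xx", 0.1]}, "unparseable-numeric"),
    ])
    def test_invalid_rows_dropped_with_reason(self, tmp_path, bad, reason):
        df = VALID.copy()
        for col, vals in bad.items():
            df[col] = vals
        table = read_sumstats(_write(tmp_path, df), "quantitative")
        assert len(table) == 2
        assert table.drop_reasons == {reason: 1}

    def test_round_trip(self, tmp_path):
        t1 = read_sumstats(_write(tmp_path, VALID), "quantitative")
        out = tmp_path / "rt.tsv"
        write_sumstats(t1, out)
        t2 = read_sumstats(out, "quantitative")
        pd.testing.assert_frame_equal(t1.df, t2.df)


class TestSelectInstruments:
    def test_strict_pvalue_inequality(self):
        table = make_table(p=[1e-9, 1e-7, 5e-8])
        assert select_instruments(table, 5e-8, 0.01) == ["rs1"]

    def test_maf_filter_uses_minor_allele(self):
        table = make_table(eaf=[0.005, 0.995, 0.3], p=[1e-9, 1e-9, 1e-9])
        assert select_instruments(table, 5e-8, 0.01) == ["rs3"]

    def test_empty_result_is_valid(self):
        table = make_table(p=[0.5, 0.6, 0.7])
        assert select_instruments(table) == []


class TestClump:
    def test_ld_partner_within_window_removed(self):
        table = make_table(pos=[1000, 6000, 3000], p=[1e-10, 1e-8, 1e-6],
                           chr=["1", "1", "9"])
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, np.sqrt(0.5)],
                                                [np.sqrt(0.5), 1.0]]))
        assert clump(table, ld, r2_threshold=0.001, window_kb=10) == \
            ["rs1", "rs3"]

    def test_outside_window_kept_regardless_of_ld(self):
        table = make_table(chr=["1", "1", "9"],
                           pos=[1000, 15_001_000, 99_000],
                           p=[1e-10, 1e-8, 1e-6])
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.99], [0.99, 1.0]]))
        kept = clump(table, ld, r2_threshold=0.001, window_kb=10_000)
        assert set(kept) == {"rs1", "rs2", "rs3"}

    def test_tied_pvalues_break_by_position(self):
        table = make_table(chr=["1", "1", "1"], pos=[5000, 1000, 3000],
                           p=[1e-8, 1e-8, 1e-8])
        ld = LDMatrix(["rs1", "rs2", "rs3"],
                      0.99 * np.ones((3, 3)) + 0.01 * np.eye(3))
        assert clump(table, ld, r2_threshold=0.001, window_kb=10) == ["rs2"]

    def test_missing_ld_snps_treated_independent(self):
        table = make_table(chr=["1", "1", "1"], pos=[1000, 2000, 3000],
                           p=[1e-10, 1e-9, 1e-8])
        kept = clump(table, LDMatrix(["rs1"], np.ones((1, 1))),
                     r2_threshold=0.001, window_kb=10)
        assert set(kept) == {"rs1", "rs2", "rs3"}

    def test_r2_threshold_one_keeps_everything(self):
        table = make_table(chr=["1"] * 3, pos=[1000, 2000, 3000])
        ld = LDMatrix(["rs1", "rs2", "rs3"],
                      0.98 * np.ones((3, 3)) + 0.02 * np.eye(3))
        assert len(clump(table, ld, r2_threshold=1.0, window_kb=0)) == 3
        # r2=0: one SNP per window-connected component
        assert len(clump(table, ld, r2_threshold=0.0, window_kb=10)) == 1


class TestCisWindow:
    def test_flank_inclusion(self):
        pred = cis_window(("1", 1000, 2000), 1_000_000)
        assert pred("1", 500_000)
        assert pred("1", 1_002_000)       # boundary is closed
        assert not pred("1", 1_200_000)
        assert not pred("2", 1500)

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            cis_window(("1", 1000, 2000), -1)


class TestHarmonize:
    def _pair(self, out_a1, out_a2, out_beta, out_eaf=0.7, exp_eaf=0.3):
        exposure = make_table(eaf=[exp_eaf] * 3)
        outcome = make_table(
            trait_id="out", a1=[out_a1, "A", "A"], a2=[out_a2, "G", "G"],
            beta=[out_beta, 0.1, 0.1], eaf=[out_eaf, 0.3, 0.3])
        return exposure, outcome

    def test_swapped_alleles_negate_beta(self):
        exposure, outcome = self._pair("G", "A", 0.2)
        hs = harmonize(exposure, outcome, ["rs1"])
        assert hs.instruments[0].beta_outcome == pytest.approx(-0.2)

    def test_strand_complement_resolved(self):
        # exposure A/G vs outcome T/C: complement, same orientation
        exposure, outcome = self._pair("T", "C", 0.2)
        hs = harmonize(exposure, outcome, ["rs1"])
        assert hs.instruments[0].beta_outcome == pytest.approx(0.2)

    def test_allele_mismatch_dropped(self):
        exposure, outcome = self._pair("A", "C", 0.2)
        hs = harmonize(exposure, outcome, ["rs1"])
        assert hs.dropped == [("rs1", "allele-mismatch")]

    def test_palindromic_midband_dropped(self):
        exposure = make_table(a1=["A"] * 3, a2=["T"] * 3, eaf=[0.5] * 3)
        outcome = make_table(trait_id="out", a1=["A"] * 3, a2=["T"] * 3,
                             eaf=[0.5] * 3)
        hs = harmonize(exposure, outcome, ["rs1"], palindrome_eaf_band=0.08)
        assert ("rs1", "palindromic-ambiguous") in hs.dropped

    def test_palindromic_clear_frequencies_kept(self):
        exposure = make_table(a1=["A"] * 3, a2=["T"] * 3, eaf=[0.2] * 3)
        outcome = make_table(trait_id="out", a1=["A"] * 3, a2=["T"] * 3,
                             eaf=[0.25] * 3)
        hs = harmonize(exposure, outcome, ["rs1"])
        assert hs.n_snp == 1

    def test_missing_outcome_dropped_and_partition_holds(self):
        exposure = make_table()
        outcome = make_table(trait_id="out").restrict(["rs1", "rs2"])
        hs = harmonize(exposure, outcome, ["rs1", "rs2", "rs3"])
        assert {i.snp_id for i in hs.instruments} | \
            {s for s, _ in hs.dropped} == {"rs1", "rs2", "rs3"}
        assert ("rs3", "missing-outcome") in hs.dropped

    def test_idempotent(self):
        exposure, outcome = self._pair("G", "A", 0.2)
        hs1 = harmonize(exposure, outcome, ["rs1", "rs2", "rs3"])
        # rebuild an outcome table that is already aligned, re-harmonize
        aligned = exposure.df.copy()
        aligned["beta"] = [i.beta_outcome for i in hs1.instruments]
        aligned["se"] = [i.se_outcome for i in hs1.instruments]
        from targetmr.sumstats import SumstatsTable
        out2 = SumstatsTable("out", "quantitative", aligned)
        hs2 = harmonize(exposure, out2, [i.snp_id for i in hs1.instruments])
        for a, b in zip(hs1.instruments, hs2.instruments):
            assert a.beta_outcome == pytest.approx(b.beta_outcome)

    @given(beta=st.floats(-1, 1, allow_nan=False),
           eaf=st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_sign_flip_invariance(self, beta, eaf):
        """Flipping effect/other alleles and negating beta in the raw
        outcome leaves the harmonized set unchanged."""
        exposure = make_table()
        out1 = make_table(trait_id="out", beta=[beta, 0.1, 0.1],
                          eaf=[eaf, 0.3, 0.3])
        flipped = out1.df.copy()
        flipped.loc[0, ["a1", "a2"]] = ["G", "A"]
        flipped.loc[0, "beta"] = -beta
        flipped.loc[0, "eaf"] = 1 - eaf
        from targetmr.sumstats import SumstatsTable
        out2 = SumstatsTable("out", "quantitative", flipped)
        h1 = harmonize(exposure, out1, ["rs1"])
        h2 = harmonize(exposure, out2, ["rs1"])
        assert h1.instruments[0].beta_outcome == pytest.approx(
            h2.instruments[0].beta_outcome)
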