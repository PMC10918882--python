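"""Summary-statistics I/O, instrument selection and harmonization."""

import numpy as np
import pandas as pd
import pytest

from twostepmr import (
    EmptyHarmonizationError,
    EmptyInstrumentError,
    LDInfo,
    SumStatsFormatError,
    exclude_outcome_significant,
    harmonize,
    read_sumstats,
    select_instruments,
    write_sumstats,
)
from twostepmr.simulate import SimulationConfig, simulate_mediation_gwas

from conftest import make_table


class TestReadWrite:
    def test_header_only_file_gives_empty_valid_table(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n")
        t = read_sumstats(p, trait_id="t")
        assert t.n_snp == 0
        assert t.trait_id == "t"

    def test_single_row_round_trip(self, tmp_path):
        p = tmp_path / "one.tsv"
        p.write_text("SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
                     "rs1\tA\tG\t0.3\t0.1\t0.02\t5e-7\t1000\n")
        t = read_sumstats(p)
        q = tmp_path / "two.tsv"
        write_sumstats(t, q)
        t2 = read_sumstats(q)
        pd.testing.assert_frame_equal(t.df, t2.df)

    def test_generated_fixture_round_trips_field_by_field(self, tmp_path):
        exp, _, _, _ = simulate_mediation_gwas(SimulationConfig(J=100, seed=3))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_sumstats(exp, p1)
        t1 = read_sumstats(p1, trait_id=exp.trait_id)
        write_sumstats(t1, p2)
        t2 = read_sumstats(p2, trait_id=exp.trait_id)
        pd.testing.assert_frame_equal(t1.df, t2.df)
        pd.testing.assert_frame_equal(exp.df.reset_index(drop=True), t1.df)

    def test_two_writes_are_byte_identical(self, tmp_path):
        exp, _, _, _ = simulate_mediation_gwas(SimulationConfig(J=200, seed=4))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_sumstats(exp, p1)
        write_sumstats(exp, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("SNP\tEA\tOA\tBETA\nrs1\tA\tG\t0.1\n")
        with pytest.raises(SumStatsFormatError, match="SE"):
            read_sumstats(p)

    def test_invalid_rows_rejected_with_reasons(self, tmp_path):
        p = tmp_path / "mix.tsv"
        p.write_text(
            "SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
            "rs1\tA\tG\t0.3\t0.1\t0.02\t0.5\t1000\n"
            "rs2\tA\tG\t0.3\t0.1\t-1\t0.5\t1000\n"   # bad SE
            "rs3\tA\tA\t0.3\t0.1\t0.02\t0.5\t1000\n"  # same alleles
            "rs4\tA\tG\t1.5\t0.1\t0.02\t0.5\t1000\n"  # bad EAF
            "rs1\tA\tG\t0.3\t0.1\t0.02\t0.5\t1000\n"  # duplicate
        )
        t = read_sumstats(p)
        assert t.n_snp == 1
        reasons = set(t.rejected["reason"])
        assert reasons == {"se not > 0", "effect_allele == other_allele",
                           "eaf outside (0,1)", "duplicate snp_id"}

    def test_missing_p_recomputed_from_beta_se(self, tmp_path):
        p = tmp_path / "nop.tsv"
        p.write_text("SNP\tEA\tOA\tBETA\tSE\nrs1\tA\tG\t0.1\t0.02\n")
        t = read_sumstats(p)
        from scipy import stats
        assert t.df["pvalue"].iloc[0] == pytest.approx(2 * stats.norm.sf(5.0))

    def test_column_aliases(self, tmp_path):
        p = tmp_path / "alias.tsv"
        p.write_text("rsid\teffect_allele\tother_allele\tb\tstderr\n"
                     "rs1\tA\tG\t0.1\t0.02\n")
        t = read_sumstats(p, column_map={"rsid": "SNP", "effect_allele": "EA",
                                         "other_allele": "OA", "b": "BETA",
                                         "stderr": "SE"})
        assert t.df["beta"].iloc[0] == 0.1


class TestSelectInstruments:
    def test_threshold_boundary(self):
        t = make_table("x", [0.1, 0.1], [0.01, 0.01], pvalue=[4e-8, 6e-8])
        assert select_instruments(t, p_threshold=5e-8) == ["rs1"]

    def test_all_above_threshold_raises(self):
        t = make_table("x", [0.01, 0.01], [0.01, 0.01], pvalue=[0.5, 0.2])
        with pytest.raises(EmptyInstrumentError):
            select_instruments(t, p_threshold=5e-8)

    def test_no_ld_keeps_all_significant_with_warning(self, caplog):
        t = make_table("x", [0.1] * 3, [0.01] * 3, pvalue=[1e-9, 1e-10, 1e-8])
        with caplog.at_level("WARNING"):
            got = select_instruments(t)
        assert set(got) == {"rs1", "rs2", "rs3"}
        assert any("independent" in r.message for r in caplog.records)

    @staticmethod
    def _greedy_oracle(table, ld, clump_r2, clump_kb):
        # independent re-statement of the clumping rule: scan by (p, snp_id),
        # keep unless correlated with an already-kept SNP within the window
        df = table.df.sort_values(["pvalue", "snp_id"]).reset_index(drop=True)
        kept = []
        for _, row in df.iterrows():
            bad = False
            for k in kept:
                same_chr = row["chrom"] == k["chrom"]
                close = abs(row["pos"] - k["pos"]) <= clump_kb * 1000
                if same_chr and close and ld.get(row["snp_id"], k["snp_id"]) >= clump_r2:
                    bad = True
            if not bad:
                kept.append(row)
        return [k["snp_id"] for k in kept]

    def test_clumping_matches_brute_force_oracle(self, rng):
        J = 10
        pos = np.sort(rng.integers(1, 5_000_000, J))
        t = make_table("x", [0.1] * J, [0.01] * J,
                       pvalue=rng.uniform(1e-12, 1e-9, J), pos=pos)
        ld = LDInfo()
        ids = t.df["snp_id"].tolist()
        for i in range(J):
            for j in range(i + 1, J):
                if rng.random() < 0.4:
                    ld.set(ids[i], ids[j], float(rng.uniform(0, 1)))
        got = select_instruments(t, ld=ld, clump_r2=0.3, clump_kb=2_000)
        expect = self._greedy_oracle(t, ld, 0.3, 2_000)
        assert got == expect

    def test_clumping_is_row_order_independent(self, rng):
        J = 8
        t = make_table("x", [0.1] * J, [0.01] * J,
                       pvalue=rng.uniform(1e-12, 1e-9, J),
                       pos=np.arange(J) * 100_000)
        ld = LDInfo()
        ids = t.df["snp_id"].tolist()
        for i in range(J - 1):
            ld.set(ids[i], ids[i + 1], 0.9)
        base = select_instruments(t, ld=ld, clump_r2=0.5, clump_kb=10_000)
        shuffled = t.df.sample(frac=1.0, random_state=0)
        t2 = make_table("x", shuffled["beta"], shuffled["se"],
                        pvalue=shuffled["pvalue"], snp_ids=shuffled["snp_id"].tolist(),
                        pos=shuffled["pos"].to_numpy())
        assert select_instruments(t2, ld=ld, clump_r2=0.5, clump_kb=10_000) == base

    def test_far_apart_snps_not_clumped_even_with_high_r2(self):
        t = make_table("x", [0.1, 0.1], [0.01, 0.01], pvalue=[1e-10, 1e-9],
                       pos=np.array([1_000_000, 500_000_000]))
        ld = LDInfo()
        ld.set("rs1", "rs2", 0.99)
        assert select_instruments(t, ld=ld, clump_r2=0.001, clump_kb=10_000) == ["rs1", "rs2"]


class TestHarmonize:
    def test_identical_orientation_keeps_betas(self):
        e = make_table("X", [0.1, -0.2], [0.01, 0.01])
        o = make_table("Y", [0.05, 0.07], [0.01, 0.01])
        h = harmonize(e, o, ["rs1", "rs2"])
        assert h.orientation_log == {"rs1": "kept", "rs2": "kept"}
        np.testing.assert_allclose(h.beta_out, [0.05, 0.07])
        np.testing.assert_allclose(h.beta_exp[:, 0], [0.1, -0.2])

    def test_swapped_alleles_flip_outcome_beta(self):
        e = make_table("X", [0.1], [0.01], ea="A", oa="G")
        o = make_table("Y", [0.05], [0.01], ea="G", oa="A", eaf=0.7)
        h = harmonize(e, o, ["rs1"])
        assert h.orientation_log["rs1"] == "flipped"
        assert h.beta_out[0] == pytest.approx(-0.05)

    def test_strand_complement_match(self):
        e = make_table("X", [0.1], [0.01], ea="A", oa="G")
        o = make_table("Y", [0.05], [0.01], ea="T", oa="C")
        h = harmonize(e, o, ["rs1"])
        assert h.beta_out[0] == pytest.approx(0.05)

    def test_palindromic_resolved_by_eaf_disagreement(self):
        e = make_table("X", [0.1], [0.01], ea="A", oa="T", eaf=0.30)
        o = make_table("Y", [0.05], [0.01], ea="A", oa="T", eaf=0.68)
        h = harmonize(e, o, ["rs1"])
        assert h.orientation_log["rs1"] == "flipped"
        assert h.beta_out[0] == pytest.approx(-0.05)

    def test_palindromic_eaf_agreement_kept(self):
        e = make_table("X", [0.1], [0.01], ea="A", oa="T", eaf=0.30)
        o = make_table("Y", [0.05], [0.01], ea="A", oa="T", eaf=0.25)
        h = harmonize(e, o, ["rs1"])
        assert h.beta_out[0] == pytest.approx(0.05)

    def test_palindromic_ambiguous_eaf_dropped(self):
        e = make_table("X", [0.1, 0.1], [0.01, 0.01], ea="A", oa="T", eaf=0.50)
        o = make_table("Y", [0.05, 0.05], [0.01, 0.01], ea="A", oa="T", eaf=0.50)
        with pytest.raises(EmptyHarmonizationError):
            harmonize(e, o, ["rs1"])
        # with a second resolvable SNP the ambiguous one is dropped, not fatal
        e2 = make_table("X", [0.1, 0.1], [0.01, 0.01],
                        ea="A", oa="G", eaf=0.3)
        e2.df.loc[0, ["effect_allele", "other_allele", "eaf"]] = ["A", "T", 0.5]
        o2 = make_table("Y", [0.05, 0.05], [0.01, 0.01], ea="A", oa="G", eaf=0.3)
        o2.df.loc[0, ["effect_allele", "other_allele", "eaf"]] = ["A", "T", 0.5]
        h = harmonize(e2, o2, ["rs1", "rs2"])
        assert h.snp_ids == ["rs2"]
        assert h.orientation_log["rs1"] == "dropped-palindromic"

    def test_missing_snp_dropped_and_logged(self):
        e = make_table("X", [0.1, 0.2], [0.01, 0.01])
        o = make_table("Y", [0.05], [0.01], snp_ids=["rs1"])
        h = harmonize(e, o, ["rs1", "rs2"])
        assert h.snp_ids == ["rs1"]
        assert h.orientation_log["rs2"] == "dropped-missing"

    def test_allele_mismatch_dropped(self):
        e = make_table("X", [0.1, 0.1], [0.01, 0.01], ea="A", oa="G")
        o = make_table("Y", [0.05, 0.05], [0.01, 0.01], ea="A", oa="G")
        o.df.loc[0, ["effect_allele", "other_allele"]] = ["A", "C"]
        h = harmonize(e, o, ["rs1", "rs2"])
        assert h.orientation_log["rs1"] == "dropped-mismatch"
        assert h.snp_ids == ["rs2"]

    def test_orientation_gauge_symmetry(self):
        """Flipping every outcome record's alleles + beta leaves the result invariant."""
        e = make_table("X", [0.1, -0.2, 0.3], [0.01, 0.02, 0.01], ea="A", oa="G")
        o = make_table("Y", [0.05, 0.07, -0.01], [0.01, 0.01, 0.02],
                       ea="A", oa="G", eaf=0.3)
        h1 = harmonize(e, o, ["rs1", "rs2", "rs3"])
        flipped = o.df.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[["other_allele", "effect_allele"]].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        o2 = make_table("Y", flipped["beta"], flipped["se"])
        o2.df = flipped
        h2 = harmonize(e, o2, ["rs1", "rs2", "rs3"])
        np.testing.assert_allclose(h1.beta_out, h2.beta_out)
        np.testing.assert_allclose(h1.beta_exp, h2.beta_exp)

    def test_harmonization_idempotent(self):
        """Harmonizing the same already-consistent tables twice changes nothing."""
        e = make_table("X", [0.1, -0.2], [0.01, 0.01])
        o = make_table("Y", [0.05, 0.07], [0.01, 0.01])
        h1 = harmonize(e, o, ["rs1", "rs2"])
        h2 = harmonize(e, o, ["rs1", "rs2"])
        np.testing.assert_array_equal(h1.beta_out, h2.beta_out)
        assert h1.orientation_log == h2.orientation_log


class TestExcludeOutcomeSignificant:
    def test_strongly_associated_snp_removed(self):
        from conftest import make_hset
        h = make_hset([0.1, 0.1], [0.01, 0.01], [0.12, 0.001], [0.02, 0.02],
                      p_out=np.array([1e-9, 0.5]))
        out = exclude_outcome_significant(h, 5e-8)
        assert out.snp_ids == ["rs2"]

    def test_unassociated_set_unchanged(self):
        from conftest import make_hset
        h = make_hset([0.1, 0.1], [0.01, 0.01], [0.01, 0.01], [0.02, 0.02])
        out = exclude_outcome_significant(h, 5e-8)
        assert out.snp_ids == h.snp_ids

    def test_mixed_fixture_matches_brute_force(self, rng):
        from conftest import make_hset
        from scipy import stats
        J = 40
        by = rng.normal(0, 0.05, J)
        sy = np.full(J, 0.01)
        h = make_hset(np.full(J, 0.1), np.full(J, 0.01), by, sy)
        out = exclude_outcome_significant(h, 5e-8)
        expect = int(np.sum(2 * stats.norm.sf(np.abs(by / sy)) >= 5e-8))
        assert out.n_snp == expect
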