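"""Summary-statistics IO, QC and cross-population harmonization."""

import numpy as np
import pandas as pd
import pytest

from crosspop import exclude_mhc, harmonize_pair, qc_filter, read_sumstats

from conftest import make_sumstats

HEADER = "snp_id chrom bp effect_allele other_allele beta se p maf n"


def write_file(tmp_path, lines, name="ss.txt"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadSumstats:
    def test_well_formed_file(self, tmp_path):
        path = write_file(tmp_path, [
            HEADER,
            "rs1 1 100 A G 0.1 0.02 1e-6 0.3 10000",
            "rs2 1 200 C T -0.05 0.01 2e-5 0.1 10000",
            "rs3 2 100 G A 0.0 0.03 1.0 0.2 10000",
        ])
        df = read_sumstats(path)
        assert len(df) == 3
        assert df.attrs["n_dropped"] == 0
        assert list(df["snp_id"]) == ["rs1", "rs2", "rs3"]
        np.testing.assert_allclose(df["z"], df["beta"] / df["se"])

    def test_unparseable_row_dropped_and_counted(self, tmp_path):
        path = write_file(tmp_path, [
            HEADER,
            "rs1 1 100 A G 0.1 0.02 1e-6 0.3 10000",
            "rs2 1 200 C T -0.05 NA 2e-5 0.1 10000",
            "rs3 2 100 G A 0.0 0.03 1.0 0.2 10000",
        ])
        df = read_sumstats(path)
        assert len(df) == 2
        assert df.attrs["n_dropped"] == 1

    def test_schema_remap_matches_unshuffled(self, tmp_path):
        p1 = write_file(tmp_path, [
            HEADER,
            "rs1 1 100 A G 0.1 0.02 1e-6 0.3 10000",
        ], "a.txt")
        p2 = write_file(tmp_path, [
            "SE BETA ID CHR POS A1 A2 P FRQ N",
            "0.02 0.1 rs1 1 100 A G 1e-6 0.3 10000",
        ], "b.txt")
        schema = {"ID": "snp_id", "CHR": "chrom", "POS": "bp", "A1": "effect_allele",
                  "A2": "other_allele", "BETA": "beta", "SE": "se", "P": "p",
                  "FRQ": "maf", "N": "n"}
        a = read_sumstats(p1)
        b = read_sumstats(p2, schema=schema)
        pd.testing.assert_frame_equal(a[sorted(a.columns)], b[sorted(a.columns)])

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = write_file(tmp_path, ["snp_id beta p", "rs1 0.1 1e-6"])
        with pytest.raises(ValueError, match="se"):
            read_sumstats(path)

    def test_gzip_transparent(self, tmp_path):
        import gzip

        path = tmp_path / "ss.txt.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(HEADER + "\nrs1 1 100 A G 0.1 0.02 1e-6 0.3 10000\n")
        assert len(read_sumstats(path)) == 1


class TestQcFilter:
    def base_rows(self):
        return [
            dict(snp_id="rs1", chrom="1", bp=100, effect_allele="A",
                 other_allele="G", beta=0.1, se=0.02, maf=0.3),
            dict(snp_id="rs2", chrom="1", bp=200, effect_allele="C",
                 other_allele="T", beta=0.05, se=0.02, maf=0.2),
        ]

    def test_duplicates_removed_entirely(self, tiny_panel):
        rows = self.base_rows()
        rows.append(dict(snp_id="rs1", chrom="1", bp=100, effect_allele="A",
                         other_allele="G", beta=0.9, se=0.02, maf=0.3))
        out = qc_filter(make_sumstats(rows), tiny_panel)
        assert "rs1" not in set(out["snp_id"])
        assert out.attrs["qc_removed"]["duplicated"] == 2

    def test_low_maf_removed(self, tiny_panel):
        rows = self.base_rows()
        rows[1]["maf"] = 0.005
        out = qc_filter(make_sumstats(rows), tiny_panel)
        assert set(out["snp_id"]) == {"rs1"}
        assert out.attrs["qc_removed"]["maf_below_0.01"] == 1

    def test_allele_mismatch_with_panel_removed(self, tiny_panel):
        rows = self.base_rows()
        rows[1]["effect_allele"], rows[1]["other_allele"] = "A", "G"  # panel has C/T
        out = qc_filter(make_sumstats(rows), tiny_panel)
        assert "rs2" not in set(out["snp_id"])

    def test_swapped_allele_order_allowed(self, tiny_panel):
        rows = self.base_rows()
        rows[0]["effect_allele"], rows[0]["other_allele"] = "G", "A"
        out = qc_filter(make_sumstats(rows), tiny_panel)
        assert "rs1" in set(out["snp_id"])

    def test_non_biallelic_and_no_rs_removed(self, tiny_panel):
        rows = self.base_rows()
        rows.append(dict(snp_id="rs3", chrom="1", bp=300, effect_allele="AT",
                         other_allele="C", beta=0.1, se=0.02, maf=0.3))
        rows.append(dict(snp_id="1:400", chrom="1", bp=400, effect_allele="A",
                         other_allele="C", beta=0.1, se=0.02, maf=0.3))
        out = qc_filter(make_sumstats(rows), tiny_panel)
        assert set(out["snp_id"]) == {"rs1", "rs2"}

    def test_idempotent(self, tiny_panel):
        rows = self.base_rows()
        rows[1]["maf"] = 0.005
        once = qc_filter(make_sumstats(rows), tiny_panel)
        twice = qc_filter(once, tiny_panel)
        assert list(once["snp_id"]) == list(twice["snp_id"])

    def test_missing_maf_backfilled_from_panel(self, tiny_panel):
        rows = self.base_rows()
        rows[0].pop("maf")
        rows[1].pop("maf")
        out = qc_filter(make_sumstats(rows), tiny_panel)
        assert out["maf"].notna().all()


class TestHarmonizePair:
    def pair(self, ea1="A", oa1="G", beta1=0.1, eaf1=0.3, ea2="A", oa2="G"):
        pop1 = make_sumstats([dict(snp_id="rs1", chrom="1", bp=100,
                                   effect_allele=ea1, other_allele=oa1,
                                   beta=beta1, se=0.02, eaf=eaf1,
                                   maf=min(eaf1, 1 - eaf1))])
        pop2 = make_sumstats([dict(snp_id="rs1", chrom="1", bp=100,
                                   effect_allele=ea2, other_allele=oa2,
                                   beta=0.2, se=0.01, eaf=0.4, maf=0.4)])
        return pop1, pop2

    def test_same_allele_unchanged(self):
        paired = harmonize_pair(*self.pair())
        row = paired.table.iloc[0]
        assert row["beta_1"] == pytest.approx(0.1)
        assert not row["allele_flipped"]

    def test_flip_negates_beta_and_complements_frequency(self):
        paired = harmonize_pair(*self.pair(ea1="G", oa1="A"))
        row = paired.table.iloc[0]
        assert row["beta_1"] == pytest.approx(-0.1)
        assert row["eaf_1"] == pytest.approx(0.7)
        assert row["allele_flipped"]
        assert row["effect_allele"] == "A"

    def test_irreconcilable_dropped(self):
        # rs1 is A/G in pop1 but A/C in pop2 -> dropped; rs9 matches -> kept
        pop1, pop2 = self.pair(ea1="A", oa1="G", ea2="A", oa2="C")
        extra = make_sumstats([dict(snp_id="rs9", chrom="1", bp=900,
                                    effect_allele="A", other_allele="C",
                                    beta=0.1, se=0.02, eaf=0.2, maf=0.2)])
        paired = harmonize_pair(pd.concat([pop1, extra], ignore_index=True),
                                pd.concat([pop2, extra.assign(beta=0.3)],
                                          ignore_index=True))
        assert set(paired.table["snp_id"]) == {"rs9"}
        assert paired.n_dropped == 1

    def test_zero_intersection_is_hard_error(self):
        pop1, pop2 = self.pair()
        pop2 = pop2.assign(snp_id="rs2")
        with pytest.raises(ValueError, match="zero SNPs"):
            harmonize_pair(pop1, pop2)

    def test_palindromic_high_maf_dropped(self):
        pop1 = make_sumstats([
            dict(snp_id="rs1", chrom="1", bp=100, effect_allele="A",
                 other_allele="T", beta=0.1, se=0.02, eaf=0.45, maf=0.45),
            dict(snp_id="rs2", chrom="1", bp=200, effect_allele="C",
                 other_allele="G", beta=0.1, se=0.02, eaf=0.1, maf=0.1),
        ])
        pop2 = pop1.assign(beta=0.2)
        paired = harmonize_pair(pop1, pop2)
        assert set(paired.table["snp_id"]) == {"rs2"}
        assert harmonize_pair(pop1, pop2, palindromic_maf_max=None).table.shape[0] == 2

    def test_symmetry_up_to_roles(self, paired_with_truth):
        from crosspop.simulate import population_sumstats

        paired, _ = paired_with_truth
        pop1 = population_sumstats(paired, 1)
        pop2 = population_sumstats(paired, 2)
        # introduce flips: recode population 1's alleles as seen from the other strand order
        pop1_swapped = pop1.copy()
        pop1_swapped[["effect_allele", "other_allele"]] = pop1[["other_allele", "effect_allele"]].to_numpy()
        pop1_swapped["beta"] = -pop1["beta"]
        pop1_swapped["eaf"] = 1 - pop1["eaf"]
        ab = harmonize_pair(pop1_swapped, pop2)
        ba = harmonize_pair(pop2, pop1_swapped)
        merged = ab.table.merge(ba.table, on="snp_id", suffixes=("_ab", "_ba"))
        # product sign of the paired effects is invariant to the alignment reference
        np.testing.assert_allclose(
            np.sign(merged["beta_1_ab"] * merged["beta_2_ab"]),
            np.sign(merged["beta_1_ba"] * merged["beta_2_ba"]))
        np.testing.assert_allclose(np.abs(merged["beta_1_ab"]),
                                   np.abs(merged["beta_2_ba"]), rtol=1e-12)


class TestExcludeMhc:
    @pytest.mark.parametrize("chrom,bp,kept", [
        ("6", 30_000_000, False),
        ("6", 28_499_999, True),
        ("6", 28_500_000, False),
        ("6", 33_500_000, False),
        ("6", 33_500_001, True),
        ("7", 30_000_000, True),
    ])
    def test_bounds(self, chrom, bp, kept):
        df = make_sumstats([dict(snp_id="rs1", chrom=chrom, bp=bp,
                                 effect_allele="A", other_allele="G",
                                 beta=0.1, se=0.02)])
        assert (len(exclude_mhc(df)) == 1) is kept
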