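"""LD scores, coefficients of variation, Fst and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crosspop import (
    ReferencePanel,
    generate_panels,
    group_compare,
    hudson_fst,
    ld_scores,
    pair_cv,
)


def brute_force_ld_scores(panel, window_bp=10_000_000, maf_min=0.01,
                          hwe_p_min=1e-5):
    """Independent double-loop reference for the LD score computation."""
    g = panel.genotypes.astype(float)
    n, m = g.shape
    maf = panel.maf()
    hwe = panel.hwe_pvalues()
    ok = (maf > maf_min) & (hwe > hwe_p_min) & (g.std(axis=0) > 0)
    chrom = panel.variants["chrom"].to_numpy()
    bp = panel.variants["bp"].to_numpy()
    out = np.zeros(m)
    for i in range(m):
        if g[:, i].std() == 0:
            out[i] = np.nan
            continue
        total = 0.0
        seen_self = False
        for j in range(m):
            if chrom[j] != chrom[i] or abs(bp[j] - bp[i]) > window_bp:
                continue
            if not ok[j]:
                continue
            r2 = 1.0 if i == j else np.corrcoef(g[:, i], g[:, j])[0, 1] ** 2
            total += r2 - (1 - r2) / (n - 2)
            seen_self = seen_self or i == j
        if not seen_self:
            total += 1.0
        out[i] = total
    return out


class TestLdScores:
    def test_isolated_snp_scores_one(self):
        rng = np.random.default_rng(0)
        panel = ReferencePanel(
            genotypes=rng.integers(0, 3, (60, 2)).astype(np.int8),
            variants=pd.DataFrame({"snp_id": ["rs1", "rs2"], "chrom": ["1", "2"],
                                   "bp": [100, 100], "a1": "A", "a2": "G"}))
        np.testing.assert_allclose(ld_scores(panel), [1.0, 1.0])

    def test_exact_duplicate_scores_two(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, 80).astype(np.int8)
        panel = ReferencePanel(
            genotypes=np.column_stack([col, col]),
            variants=pd.DataFrame({"snp_id": ["rs1", "rs2"], "chrom": "1",
                                   "bp": [100, 200], "a1": "A", "a2": "G"}))
        np.testing.assert_allclose(ld_scores(panel), [2.0, 2.0])

    def test_matches_brute_force(self, small_panels):
        panel = small_panels[0]
        np.testing.assert_allclose(ld_scores(panel), brute_force_ld_scores(panel),
                                   rtol=0, atol=1e-10, equal_nan=True)

    def test_window_limits_flanks(self):
        panel, _ = generate_panels(n1=80, n2=10, m=50, block_size=50,
                                   within_block_r2=0.5, seed=4, bp_spacing=1000)
        wide = ld_scores(panel, window_bp=1_000_000)
        narrow = ld_scores(panel, window_bp=1)
        assert np.nanmean(wide) > np.nanmean(narrow)
        np.testing.assert_allclose(narrow[~np.isnan(narrow)], 1.0)

    def test_individual_permutation_invariance(self, small_panels):
        panel = small_panels[0]
        perm = np.random.default_rng(5).permutation(panel.n_individuals)
        permuted = ReferencePanel(genotypes=panel.genotypes[perm],
                                  variants=panel.variants.copy())
        np.testing.assert_allclose(ld_scores(panel), ld_scores(permuted),
                                   atol=1e-10, equal_nan=True)


class TestPairCv:
    def test_equal_values_zero(self):
        assert pair_cv(0.3, 0.3) == 0.0

    def test_published_maf_pair(self):
        # the largest published cross-population MAF difference (PLT index SNP)
        assert pair_cv(0.492, 0.036) == pytest.approx(1.221, abs=0.001)

    @given(st.floats(0.01, 10), st.floats(0.01, 10), st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, a, b, scale):
        assert pair_cv(a * scale, b * scale) == pytest.approx(pair_cv(a, b), rel=1e-9)

    def test_non_positive_mean_flagged_nan(self):
        assert np.isnan(pair_cv(0.0, 0.0))

    def test_folding_invariance_for_maf(self):
        # relabeling the minor allele leaves folded-MAF CV unchanged
        f1, f2 = 0.42, 0.31
        assert pair_cv(min(f1, 1 - f1), min(f2, 1 - f2)) == pytest.approx(
            pair_cv(min(1 - f1, f1), min(1 - f2, f2)))


class TestHudsonFst:
    def test_no_differentiation_near_zero(self):
        assert abs(hudson_fst(0.3, 100_000, 0.3, 100_000)) < 1e-4
        assert hudson_fst(0.3, 1_000, 0.3, 1_000) < 0  # sampling correction

    def test_fixation(self):
        assert hudson_fst(1.0, 1_000, 0.0, 1_000) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        f1, n1, f2, n2 = 0.3, 1_008, 0.5, 1_006
        num = (f1 - f2) ** 2 - f1 * (1 - f1) / (n1 - 1) - f2 * (1 - f2) / (n2 - 1)
        den = f1 * (1 - f2) + f2 * (1 - f1)
        assert hudson_fst(f1, n1, f2, n2) == pytest.approx(num / den, abs=1e-12)

    def test_population_symmetry(self):
        assert hudson_fst(0.2, 500, 0.6, 700) == pytest.approx(
            hudson_fst(0.6, 700, 0.2, 500), abs=1e-15)

    def test_undefined_when_both_fixed_same(self):
        assert np.isnan(hudson_fst(0.0, 100, 0.0, 100))

    def test_mean_fst_increases_with_divergence_parameter(self):
        means = []
        for fst_level in (0.0, 0.01, 0.05, 0.1):
            per_seed = []
            for seed in range(5):
                p1, p2 = generate_panels(n1=150, n2=150, m=400,
                                         fst_level=fst_level, seed=100 + seed)
                fst = hudson_fst(p1.allele_freq(), 300, p2.allele_freq(), 300)
                per_seed.append(np.nanmean(fst))
            means.append(np.mean(per_seed))
        assert np.all(np.diff(means) > 0)


class TestGroupCompare:
    def metrics(self, sig, non, phenotype="A"):
        return pd.DataFrame({
            "phenotype": phenotype,
            "group": ["significant"] * len(sig) + ["non_significant"] * len(non),
            "fst": np.concatenate([sig, non]),
        })

    def test_identical_groups_p_one(self):
        vals = np.ones(30)
        res = group_compare(self.metrics(vals, vals), "fst")
        assert res["per_phenotype"]["p"].iloc[0] == pytest.approx(1.0)

    def test_shifted_groups_detected(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sig = rng.standard_normal(200)
            non = rng.standard_normal(200) + 1.0
            res = group_compare(self.metrics(sig, non), "fst")
            hits += res["per_phenotype"]["p"].iloc[0] < 1e-6
        assert hits >= 95

    def test_sign_test_matches_binomial_oracle(self):
        rng = np.random.default_rng(2)
        frames = []
        low = 24  # phenotypes where the significant group sits lower
        for i in range(31):
            shift = -3.0 if i < low else 3.0
            frames.append(self.metrics(rng.standard_normal(40) + shift,
                                       rng.standard_normal(40), phenotype=f"P{i}"))
        res = group_compare(pd.concat(frames, ignore_index=True), "fst")
        assert res["n_significant_group_lower"] == low
        assert res["share_significant_group_lower"] == pytest.approx(24 / 31)
        assert res["sign_test_p"] == pytest.approx(
            stats.binomtest(low, 31, 0.5).pvalue)

    def test_literal_mcnemar_flag(self):
        rng = np.random.default_rng(3)
        frames = [self.metrics(rng.standard_normal(30) - 1,
                               rng.standard_normal(30), phenotype=f"P{i}")
                  for i in range(10)]
        res = group_compare(pd.concat(frames, ignore_index=True), "fst",
                            literal_mcnemar=True)
        assert res["mcnemar_chi2"] == pytest.approx(10.0)  # 10 vs 0 discordant

    def test_empty_group_skipped(self):
        df = self.metrics(np.ones(5), np.array([]))
        res = group_compare(df, "fst")
        assert len(res["per_phenotype"]) == 0
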