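"""HEIDI: member selection, the d-covariance, the weighted-chi-square null,
and the end-to-end heterogeneity test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smrkit.heidi import (
    HeidiParams,
    HeidiSnpSet,
    heidi_test,
    select_heidi_snps,
    weighted_chi2_sf,
    zd_covariance,
)
from smrkit.ld_reference import LdMatrix
from smrkit.simulate import SimScenario
from smrkit.sumstats_io import HarmonizedLocus

from conftest import FAST, locus_and_ld


def build_locus(b_zx, se_zx, p_eqtl, b_zy, se_zy, r):
    """Hand-built harmonized locus + LD matrix (index 0 is the top SNP)."""
    m = len(b_zx)
    snps = pd.DataFrame({
        "snp_id": [f"rs{j + 1}" for j in range(m)],
        "chrom": "1", "bp": np.arange(m) * 1000 + 1, "a1": "A", "a2": "G",
        "freq_eqtl": 0.3, "freq_gwas": 0.3,
        "b_zx": b_zx, "se_zx": se_zx, "p_eqtl": p_eqtl,
        "b_zy": b_zy, "se_zy": se_zy,
        "p_gwas": 2 * stats.norm.sf(np.abs(np.asarray(b_zy) / se_zy)),
        "n": 10000,
    })
    top = int(np.argmin(p_eqtl))
    locus = HarmonizedLocus("pr1", "G1", "1", 1, snps, top)
    ld = LdMatrix(snps["snp_id"].tolist(), np.asarray(r, float))
    return locus, ld


class TestSelectSnps:
    def test_threshold_excludes_weak_members(self):
        m = 6
        locus, ld = build_locus([0.5] + [0.2] * 5, [0.02] * 6,
                                [1e-100] + [1e-2] * 5,
                                [0.1] * 6, [0.01] * 6, np.eye(6))
        s = select_heidi_snps(locus, ld, p_incl=1.6e-3)
        assert s.n_members == 0 and s.top_index == 0

    def test_high_ld_pair_pruned_keeping_smaller_p(self):
        r = np.eye(3)
        r[1, 2] = r[2, 1] = 0.996  # r^2 ~ 0.992
        locus, ld = build_locus([0.5, 0.3, 0.3], [0.02] * 3,
                                [1e-100, 1e-20, 1e-10],
                                [0.1] * 3, [0.01] * 3, r)
        s = select_heidi_snps(locus, ld, r2_prune_high=0.9)
        assert s.member_indices == [1]

    def test_members_in_high_ld_with_top_dropped(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.99
        locus, ld = build_locus([0.5, 0.49, 0.3], [0.02] * 3,
                                [1e-100, 1e-90, 1e-10],
                                [0.1] * 3, [0.01] * 3, r)
        s = select_heidi_snps(locus, ld)
        assert s.member_indices == [2]

    def test_brute_force_recount_on_simulated_locus(self):
        locus, ld = locus_and_ld(SimScenario(model="pleiotropy", seed=9, **FAST))
        params = HeidiParams()
        s = select_heidi_snps(locus, ld, p_incl=params.p_incl,
                              r2_prune_high=params.r2_prune_high)
        # independent re-count: every member passes the p threshold, no kept
        # pair (incl. top) exceeds the r^2 prune level
        p = locus.snps["p_eqtl"].to_numpy()
        assert all(p[i] < params.p_incl for i in s.member_indices)
        sub = ld.subset(locus.snps["snp_id"].tolist())
        kept = s.all_indices()
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                assert sub.r2()[kept[a], kept[b]] <= params.r2_prune_high
        # and no excluded sub-threshold SNP survives both rules
        for i in range(locus.n_snps):
            if i in kept or p[i] >= params.p_incl:
                continue
            rank_before = [j for j in kept
                           if (p[j], locus.snps["snp_id"].iloc[j])
                           < (p[i], locus.snps["snp_id"].iloc[i])]
            assert any(sub.r2()[i, j] > params.r2_prune_high
                       for j in rank_before)


class TestZdCovariance:
    def test_independence_closed_form(self):
        # two members uncorrelated with each other and with the top SNP:
        # the only shared term is the top SNP's variance, so
        # corr(d_1, d_2) = var(b_xy_top) / (var(b_xy_top) + var(b_xy_member))
        b_zx, se_zx = [0.5, 0.5, 0.5], [0.02] * 3
        b_zy, se_zy = [0.1, 0.1, 0.1], [0.01] * 3
        locus, ld = build_locus(b_zx, se_zx, [1e-100, 1e-20, 1e-20],
                                b_zy, se_zy, np.eye(3))
        s = HeidiSnpSet(top_index=0, member_indices=[1, 2])
        corr, var = zd_covariance(locus, s, ld)
        v = (se_zy[0] / b_zx[0]) ** 2 + (b_zy[0] * se_zx[0] / b_zx[0] ** 2) ** 2
        expected = v / (v + v)  # identical variances at all three SNPs
        assert corr[0, 1] == pytest.approx(expected)
        np.testing.assert_allclose(var, 2 * v)

    def test_symmetric_unit_diagonal(self, pleiotropy_locus):
        locus, ld = pleiotropy_locus
        s = select_heidi_snps(locus, ld)
        corr, var = zd_covariance(locus, s, ld)
        np.testing.assert_allclose(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert np.all(var > 0)

    def test_against_monte_carlo_covariance(self):
        # empirical covariance of d over repeated summary-statistic draws
        # at a fixed locus matches the delta-method matrix entrywise
        rng = np.random.default_rng(314)
        r = np.array([[1.0, 0.6, 0.3, 0.1],
                      [0.6, 1.0, 0.5, 0.2],
                      [0.3, 0.5, 1.0, 0.4],
                      [0.1, 0.2, 0.4, 1.0]])
        b_zx_true = np.array([0.5, 0.35, 0.3, 0.25])
        b_xy = 0.2
        b_zy_true = b_xy * b_zx_true
        se_zx = np.full(4, 0.015)
        se_zy = np.full(4, 0.01)
        locus, ld = build_locus(b_zx_true, se_zx, [1e-200, 1e-80, 1e-60, 1e-40],
                                b_zy_true, se_zy, r)
        s = HeidiSnpSet(top_index=0, member_indices=[1, 2, 3])
        corr, var = zd_covariance(locus, s, ld)
        cov_delta = corr * np.sqrt(np.outer(var, var))

        n_draws = 20_000
        chol = np.linalg.cholesky(r)
        bzx = b_zx_true + (rng.standard_normal((n_draws, 4)) @ chol.T) * se_zx
        bzy = b_zy_true + (rng.standard_normal((n_draws, 4)) @ chol.T) * se_zy
        bxy = bzy / bzx
        d = bxy[:, 1:] - bxy[:, [0]]
        cov_mc = np.cov(d, rowvar=False)
        mc_se = np.sqrt((np.outer(np.diag(cov_mc), np.diag(cov_mc))
                         + cov_mc ** 2) / n_draws)
        assert np.all(np.abs(cov_mc - cov_delta) < 3 * mc_se)

    def test_empty_set_rejected(self, pleiotropy_locus):
        locus, ld = pleiotropy_locus
        with pytest.raises(ValueError, match="empty"):
            zd_covariance(locus, HeidiSnpSet(top_index=locus.top_index), ld)


class TestWeightedChi2:
    def test_single_weight_reduces_to_1df(self):
        assert weighted_chi2_sf(3.841, [1.0]) == pytest.approx(0.05, rel=1e-3)

    def test_equal_weights_reduce_to_kdf(self):
        assert weighted_chi2_sf(7.815, [1, 1, 1]) == pytest.approx(0.05, rel=1e-3)

    def test_null_approximation_matches_monte_carlo_on_grid(self):
        # the default (Imhof) tail agrees with the empirical distribution
        # everywhere; two-moment Satterthwaite is a coarser fallback
        grid = [(2.0, 1.0, 0.5), (1.0, 1.0, 1.0), (5.0, 1.0, 0.2),
                (3.0, 2.0, 1.0, 0.5, 0.1), (1.0, 0.1)]
        for weights in grid:
            s1 = sum(weights)
            for t in (0.5 * s1, s1, 2 * s1, 10.0):
                p = weighted_chi2_sf(t, weights)
                mc = weighted_chi2_sf(t, weights, method="mc",
                                      mc_draws=10 ** 6, seed=123)
                if p >= 0.01:
                    assert abs(p - mc) < 0.005, (weights, t)
                sat = weighted_chi2_sf(t, weights, method="satterthwaite")
                assert abs(sat - p) < 0.02, (weights, t)

    def test_zero_weights_hard_error(self):
        with pytest.raises(ValueError):
            weighted_chi2_sf(1.0, [0.0, 0.0])

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            weighted_chi2_sf(1.0, [1.0, -0.5])


class TestHeidiTest:
    def test_perfectly_homogeneous_locus(self):
        # all member b_xy equal the top SNP's exactly: T = 0, p = 1
        b_zx = np.array([0.5, 0.4, 0.3, 0.25])
        b_zy = 0.2 * b_zx
        r = np.eye(4) + 0.3 - 0.3 * np.eye(4)
        locus, ld = build_locus(b_zx, [0.02] * 4,
                                [1e-100, 1e-50, 1e-30, 1e-20],
                                b_zy, [0.01] * 4, r)
        res = heidi_test(locus, ld)
        assert res.status == "ok"
        assert res.t_heidi == pytest.approx(0.0, abs=1e-12)
        assert res.p_heidi == pytest.approx(1.0)

    def test_too_few_members(self):
        locus, ld = build_locus([0.5, 0.3], [0.02] * 2, [1e-100, 1e-20],
                                [0.1, 0.06], [0.01] * 2, np.eye(2))
        res = heidi_test(locus, ld, HeidiParams(min_snps=3))
        assert res.status == "too_few_snps" and res.p_heidi is None

    def test_single_member_collapses_to_1df(self):
        locus, ld = build_locus([0.5, 0.3], [0.02] * 2, [1e-100, 1e-20],
                                [0.1, 0.09], [0.01] * 2, np.eye(2))
        res = heidi_test(locus, ld, HeidiParams(min_snps=1))
        assert res.status == "ok" and res.nsnp_used == 1
        assert res.p_heidi == pytest.approx(stats.chi2.sf(res.t_heidi, 1))

    def test_scale_invariance_of_expression_units(self, pleiotropy_locus):
        locus, ld = pleiotropy_locus
        base = heidi_test(locus, ld)
        scaled = HarmonizedLocus(
            locus.probe_id, locus.gene, locus.probe_chrom, locus.probe_bp,
            locus.snps.assign(b_zx=locus.snps["b_zx"] * 7.3,
                              se_zx=locus.snps["se_zx"] * 7.3),
            locus.top_index)
        res = heidi_test(scaled, ld)
        assert res.t_heidi == pytest.approx(base.t_heidi, rel=1e-10)
        assert res.p_heidi == pytest.approx(base.p_heidi, rel=1e-10)

    def test_allele_flip_invariance(self, pleiotropy_locus):
        # flipping one SNP's effect allele (betas, freqs, LD signs) leaves
        # the heterogeneity statistic unchanged
        locus, ld = pleiotropy_locus
        base = heidi_test(locus, ld)
        j = 3
        snps = locus.snps.copy()
        snps.loc[j, ["a1", "a2"]] = snps.loc[j, ["a2", "a1"]].to_numpy()
        snps.loc[j, "b_zx"] *= -1
        snps.loc[j, "b_zy"] *= -1
        snps.loc[j, "freq_eqtl"] = 1 - snps.loc[j, "freq_eqtl"]
        snps.loc[j, "freq_gwas"] = 1 - snps.loc[j, "freq_gwas"]
        flipped_locus = HarmonizedLocus(
            locus.probe_id, locus.gene, locus.probe_chrom, locus.probe_bp,
            snps, locus.top_index)
        r = ld.r.copy()
        pos = ld.snp_ids.index(snps.loc[j, "snp_id"])
        r[pos, :] *= -1
        r[:, pos] *= -1
        np.fill_diagonal(r, 1.0)
        res = heidi_test(flipped_locus, LdMatrix(list(ld.snp_ids), r))
        assert res.t_heidi == pytest.approx(base.t_heidi, rel=1e-10)
        assert res.p_heidi == pytest.approx(base.p_heidi, rel=1e-10)

    def test_type_one_error_under_pleiotropy(self):
        # single shared causal variant: rejections at 0.05 stay near nominal
        rej = ok = 0
        for k in range(800):
            locus, ld = locus_and_ld(SimScenario(
                model="pleiotropy", seed=700_000 + k,
                n_eqtl=3000, n_gwas=5000, n_ref=500, n_snps=30))
            res = heidi_test(locus, ld)
            if res.status == "ok":
                ok += 1
                rej += res.p_heidi < 0.05
        assert ok > 700
        assert 0.03 < rej / ok < 0.07

    def test_power_under_linkage_exceeds_null_rate(self):
        # two causal variants in LD: heterogeneity should be detected far
        # above the nominal level
        rej = ok = 0
        for k in range(150):
            locus, ld = locus_and_ld(SimScenario(
                model="linkage", seed=800_000 + k,
                n_eqtl=3000, n_gwas=5000, n_ref=500, n_snps=30))
            res = heidi_test(locus, ld)
            if res.status == "ok":
                ok += 1
                rej += res.p_heidi < 0.05
        assert rej / ok > 0.3
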