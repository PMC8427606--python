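"""HEIDI: SNP selection, delta-method covariance, statistic and null p-value."""

import copy

import numpy as np
import pytest
from scipy.stats import chi2, ks_2samp

from mirsmr import (HeidiConfig, SimConfig, bxy_covariance, heidi_pvalue,
                    heidi_statistic, run_heidi, select_heidi_snps,
                    select_top_instrument, simulate_scenario)
from mirsmr.simulate import simulate_genotypes

from test_smr import make_locus


def ar1_corr(m, rho):
    idx = np.arange(m)
    return rho ** np.abs(np.subtract.outer(idx, idx))


class TestSelection:
    def test_high_ld_snp_excluded(self):
        ld = np.array([[1.0, 0.975, 0.5],
                       [0.975, 1.0, 0.5],
                       [0.5, 0.5, 1.0]])  # r^2 to top: 0.95, 0.25
        locus = make_locus([0.5, 0.4, 0.35], [0.03] * 3, [0.1] * 3, [0.05] * 3,
                           ld=ld)
        idx = select_heidi_snps(locus, top=0)
        assert list(idx) == [0, 2]

    def test_cap_keeps_smallest_eqtl_p(self):
        m = 31
        b_zx = np.linspace(0.50, 0.20, m)  # decreasing |z| -> increasing p
        ld = np.full((m, m), 0.5)
        np.fill_diagonal(ld, 1.0)
        locus = make_locus(b_zx, [0.03] * m, [0.1] * m, [0.05] * m, ld=ld)
        idx = select_heidi_snps(locus, top=0)
        assert len(idx) == 20
        assert list(idx) == list(range(20))  # the 20 smallest eQTL p

    def test_weak_snps_excluded(self):
        # second SNP z ~ 1.7: above the p_zx ceiling
        ld = ar1_corr(2, 0.5)
        locus = make_locus([0.5, 0.05], [0.03, 0.03], [0.1, 0.1],
                           [0.05, 0.05], ld=ld)
        assert list(select_heidi_snps(locus, top=0)) == [0]

    def test_two_snp_locus_is_too_few(self):
        ld = ar1_corr(2, 0.5)
        locus = make_locus([0.5, 0.4], [0.03, 0.03], [0.1, 0.08],
                           [0.05, 0.05], ld=ld)
        res = run_heidi(locus, top=0)
        assert res.status == "too_few_snps"
        assert res.p_heidi is None


class TestCovariance:
    def test_independent_snps_have_zero_cross_covariance(self):
        locus = make_locus([0.5, 0.4], [0.02, 0.02], [0.1, 0.08], [0.03, 0.03],
                           ld=np.eye(2))
        cov = bxy_covariance(locus, np.array([0, 1]))
        assert cov[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_diagonal_is_the_delta_variance(self):
        locus = make_locus([0.5], [0.02], [0.1], [0.03])
        cov = bxy_covariance(locus, np.array([0]))
        expected = 0.03 ** 2 / 0.5 ** 2 + 0.1 ** 2 * 0.02 ** 2 / 0.5 ** 4
        assert cov[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_matches_monte_carlo_covariance(self):
        """Delta covariance within 3% of simulated b_xy covariance (1e6 draws)."""
        rng = np.random.default_rng(5)
        m = 5
        b_zx = np.array([0.50, 0.45, 0.40, 0.35, 0.30])
        b_zy = 0.2 * b_zx
        se_zx = np.full(m, 0.01)
        se_zy = np.full(m, 0.008)
        R = ar1_corr(m, 0.6)
        locus = make_locus(b_zx, se_zx, b_zy, se_zy, ld=R)
        delta_cov = bxy_covariance(locus, np.arange(m))

        L = np.linalg.cholesky(R)
        n = 1_000_000
        zx_hat = b_zx + (rng.standard_normal((n, m)) @ L.T) * se_zx
        zy_hat = b_zy + (rng.standard_normal((n, m)) @ L.T) * se_zy
        mc_cov = np.cov((zy_hat / zx_hat).T)
        np.testing.assert_allclose(delta_cov, mc_cov, rtol=0.03)

    def test_zero_instrument_effect_rejected(self):
        locus = make_locus([0.5, 0.0 + 1e-300], [0.02, 0.02], [0.1, 0.1],
                           [0.03, 0.03])
        locus.b_zx[1] = 0.0
        with pytest.raises(ZeroDivisionError):
            bxy_covariance(locus, np.array([0, 1]))


class TestStatistic:
    def test_perfect_homogeneity_gives_zero(self):
        b_zx = np.array([0.5, 0.4, 0.3])
        locus = make_locus(b_zx, [0.02] * 3, 0.2 * b_zx, [0.03] * 3,
                           ld=ar1_corr(3, 0.5))
        t, z_d, _ = heidi_statistic(locus, np.arange(3), top=0)
        assert t == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(z_d, 0.0, atol=1e-12)

    def test_single_contrast(self):
        locus = make_locus([0.5, 0.4], [0.02] * 2, [0.10, 0.02], [0.03] * 2,
                           ld=ar1_corr(2, 0.5))
        t, z_d, corr = heidi_statistic(locus, np.array([0, 1]), top=0)
        assert len(z_d) == 1
        assert t == pytest.approx(z_d[0] ** 2)
        assert corr.shape == (1, 1)

    def test_allele_flip_at_non_top_snp_is_invariant(self):
        """Recoding the effect allele at a non-top SNP (negating b_zx, b_zy
        and that SNP's LD row/column) leaves t_heidi unchanged."""
        sc = simulate_scenario(SimConfig(seed=21, model="pleiotropy",
                                         n_gwas=5000, n_eqtl=5000))
        locus = sc.to_locus()
        top = select_top_instrument(locus)
        idx = select_heidi_snps(locus, top)
        t0, _, _ = heidi_statistic(locus, idx, top)
        flipped = copy.deepcopy(locus)
        j = int(idx[idx != top][0])
        flipped.b_zx[j] *= -1
        flipped.b_zy[j] *= -1
        flipped.ld_r[j, :] *= -1
        flipped.ld_r[:, j] *= -1
        flipped.ld_r[j, j] = 1.0
        t1, _, _ = heidi_statistic(flipped, idx, top)
        assert t1 == pytest.approx(t0, rel=1e-10)


class TestPvalue:
    def test_identity_correlation_reduces_to_chisq(self):
        for m in (2, 5, 10):
            t95 = chi2.isf(0.05, df=m)
            p = heidi_pvalue(t95, np.eye(m))
            assert p == pytest.approx(0.05, abs=1e-3)

    def test_zero_statistic_single_contrast(self):
        assert heidi_pvalue(0.0, np.eye(1)) == pytest.approx(1.0)

    def test_duplicated_contrast_matches_two_zero_mixture(self):
        """Correlation-1 contrasts give the lambda = {2, 0} mixture: the
        p equals the single-contrast p at t/2, checked against Monte Carlo."""
        rng = np.random.default_rng(11)
        mc = 2.0 * rng.chisquare(1, 1_000_000)
        corr = np.ones((2, 2))
        for t in (1.0, 2.0, 4.0, 8.0, 12.0):
            p = heidi_pvalue(t, corr)
            assert p == pytest.approx(chi2.sf(t / 2.0, 1), rel=1e-10)
            p_mc = np.mean(mc > t)
            if 0.01 <= p_mc <= 0.5:
                assert p == pytest.approx(p_mc, rel=0.10)

    def test_imhof_agrees_with_satterthwaite_in_the_body(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((8, 4))
        R = np.corrcoef(A @ A.T + np.eye(8))
        lam = np.clip(np.linalg.eigvalsh(R), 0, None)
        for q in (0.5, 0.2, 0.05, 0.01, 1e-3):
            # invert the Satterthwaite approximation to land near p = q
            s1, s2 = lam.sum(), lam @ lam
            t = chi2.isf(q, s1 ** 2 / s2) * s2 / s1
            p_sat = heidi_pvalue(t, R, method="satterthwaite")
            p_imhof = heidi_pvalue(t, R, method="imhof")
            assert p_sat > 1e-4 and p_imhof > 1e-4
            assert p_sat == pytest.approx(p_imhof, rel=0.35, abs=5e-4)

    def test_all_zero_eigenvalues(self):
        assert heidi_pvalue(1.0, np.zeros((0, 0))) == 1.0


class TestNullDistribution:
    def test_statistic_follows_weighted_chisq_null(self):
        """With genotypes held fixed, resampled phenotypes under the
        single-shared-variant model give t_heidi draws matching the
        eigenvalue mixture (two-sample KS)."""
        cfg0 = SimConfig(seed=99, model="pleiotropy")
        rng = np.random.default_rng(99)
        maf = rng.uniform(*cfg0.maf_range, cfg0.m_snps)
        geno = (simulate_genotypes(cfg0.n_eqtl, cfg0.m_snps, maf, cfg0.rho, rng),
                simulate_genotypes(cfg0.n_gwas, cfg0.m_snps, maf, cfg0.rho, rng),
                simulate_genotypes(cfg0.n_ld, cfg0.m_snps, maf, cfg0.rho, rng))
        ts, lams = [], []
        for rep in range(800):
            sc = simulate_scenario(SimConfig(seed=10_000 + rep, model="pleiotropy"),
                                   genotypes=geno)
            locus = sc.to_locus()
            top = select_top_instrument(locus)
            idx = select_heidi_snps(locus, top)
            if len(idx) < 3:
                continue
            t, z_d, corr_d = heidi_statistic(locus, idx, top)
            ts.append(t)
            lam = np.clip(np.linalg.eigvalsh(corr_d), 0, None)
            lams.append(np.sort(lam)[::-1])
        assert len(ts) > 700
        k = min(len(l) for l in lams)
        lam_bar = np.mean([l[:k] for l in lams], axis=0)
        null_rng = np.random.default_rng(123)
        mixture = null_rng.chisquare(1, (100_000, k)) @ lam_bar
        assert ks_2samp(np.asarray(ts), mixture).pvalue > 0.01


class TestMonotonicity:
    def test_inflating_gwas_se_cannot_shrink_p(self):
        for seed in (2, 5, 9):
            sc = simulate_scenario(SimConfig(seed=seed, model="pleiotropy",
                                             n_gwas=5000, n_eqtl=5000))
            locus = sc.to_locus()
            top = select_top_instrument(locus)
            base = run_heidi(locus, top)
            if base.status != "tested":
                continue
            prev = base.p_heidi
            for c in (1.5, 2.0, 5.0):
                inflated = copy.deepcopy(locus)
                inflated.se_zy = locus.se_zy * c
                res = run_heidi(inflated, top)
                assert res.p_heidi >= prev - 1e-12
                prev = res.p_heidi
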