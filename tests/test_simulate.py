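"""The synthetic cis-locus generator: genotypes, marginals, scenarios, files."""

import json

import numpy as np
import pytest

from mirsmr import (SimConfig, harmonize_locus, load_ld_reference,
                    read_probe_table, read_summary_table, run_heidi,
                    select_top_instrument, simulate_genotypes,
                    simulate_scenario, smr_test)
from mirsmr.simulate import marginal_regression


class TestGenotypes:
    def test_marginals_binomial(self):
        rng = np.random.default_rng(0)
        maf = np.full(6, 0.5)
        g = simulate_genotypes(20_000, 6, maf, 0.0, rng)
        assert g.min() >= 0 and g.max() <= 2
        np.testing.assert_allclose(g.mean(axis=0), 1.0, atol=0.03)
        np.testing.assert_allclose(g.var(axis=0), 0.5, atol=0.02)

    def test_zero_rho_gives_independent_snps(self):
        rng = np.random.default_rng(1)
        g = simulate_genotypes(20_000, 8, np.full(8, 0.3), 0.0, rng)
        r = np.corrcoef(g.T)
        off = r[~np.eye(8, dtype=bool)]
        assert np.all(np.abs(off) < 0.03)

    def test_high_rho_gives_decaying_ld(self):
        rng = np.random.default_rng(2)
        g = simulate_genotypes(20_000, 10, np.full(10, 0.3), 0.9, rng)
        r = np.corrcoef(g.T)
        adjacent = np.diag(r, 1)
        distant = r[0, 9]
        assert adjacent.mean() > 0.6
        assert distant < adjacent.mean()

    def test_deterministic_given_rng_seed(self):
        a = simulate_genotypes(100, 5, np.full(5, 0.2), 0.5,
                               np.random.default_rng(7))
        b = simulate_genotypes(100, 5, np.full(5, 0.2), 0.5,
                               np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 1, np.array([0.3]), 0.5,
                               np.random.default_rng(0))


class TestMarginalRegression:
    def test_matches_polyfit_per_column(self):
        rng = np.random.default_rng(3)
        G = rng.binomial(2, 0.3, (500, 4)).astype(float)
        y = rng.standard_normal(500)
        beta, se, _ = marginal_regression(G, y, standardized=False)
        for j in range(4):
            slope = np.polyfit(G[:, j], y, 1)[0]
            assert beta[j] == pytest.approx(slope, rel=1e-9)

    def test_standardized_beta_is_per_sd(self):
        rng = np.random.default_rng(4)
        G = rng.binomial(2, 0.3, (2000, 1)).astype(float)
        y = 0.5 * G[:, 0] + rng.standard_normal(2000)
        b_raw, _, _ = marginal_regression(G, y, standardized=False)
        b_std, _, _ = marginal_regression(G, y, standardized=True)
        assert b_std[0] == pytest.approx(b_raw[0] * G[:, 0].std(), rel=1e-9)

    def test_se_scales_as_inverse_sqrt_n(self):
        """Null marginal SE tracks 1/sqrt(n) within 10% across cohort sizes."""
        ses = {}
        for n in (5_000, 20_000, 80_000):
            rng = np.random.default_rng(50)
            G = simulate_genotypes(n, 3, np.full(3, 0.3), 0.0, rng)
            y = rng.standard_normal(n)
            _, se, _ = marginal_regression(G, y)
            ses[n] = se.mean()
        for n in (5_000, 20_000, 80_000):
            assert ses[n] == pytest.approx(1.0 / np.sqrt(n), rel=0.10)
        assert ses[5_000] / ses[80_000] == pytest.approx(4.0, rel=0.10)

    def test_monomorphic_column(self):
        G = np.column_stack([np.ones(50), np.arange(50) % 3]).astype(float)
        beta, se, p = marginal_regression(G, np.random.default_rng(5).standard_normal(50))
        assert beta[0] == 0 and np.isinf(se[0]) and p[0] == 1.0


class TestScenario:
    def test_deterministic(self):
        cfg = SimConfig(seed=5, n_gwas=2000, n_eqtl=2000, n_ld=500)
        a, b = simulate_scenario(cfg), simulate_scenario(cfg)
        np.testing.assert_array_equal(a.eqtl["beta"], b.eqtl["beta"])
        np.testing.assert_array_equal(a.gwas["beta"], b.gwas["beta"])
        np.testing.assert_array_equal(a.ld.r, b.ld.r)

    def test_causal_eqtl_beta_converges(self):
        """The standardized marginal beta at the causal SNP estimates b_zx."""
        betas = [simulate_scenario(SimConfig(seed=s)).eqtl["beta"].iloc[15]
                 for s in range(30, 40)]
        assert np.mean(betas) == pytest.approx(0.3, abs=0.02)

    def test_causality_model_recovers_bxy(self):
        sc = simulate_scenario(SimConfig(seed=41, model="causality"))
        locus = sc.to_locus()
        res = smr_test(locus)
        assert res is not None
        assert res.b_xy == pytest.approx(0.3, abs=3 * res.se_xy)

    def test_linkage_model_uses_distinct_snp_at_target_ld(self):
        sc = simulate_scenario(SimConfig(seed=42, model="linkage"))
        t = sc.truth
        assert t.second_index is not None and t.second_index != t.causal_index
        assert abs(t.realized_ld - 0.3) <= 0.05
        assert sc.ld.r[t.causal_index, t.second_index] == pytest.approx(t.realized_ld)

    def test_probe_tss_at_causal_snp(self):
        sc = simulate_scenario(SimConfig(seed=43, n_gwas=500, n_eqtl=500, n_ld=300))
        assert sc.probe.tss_bp == sc.eqtl["bp"].iloc[sc.truth.causal_index]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=0, model="confounding")
        with pytest.raises(ValueError):
            SimConfig(seed=0, rho=1.0)
        with pytest.raises(ValueError):
            SimConfig(seed=0, b_zx=1.5)


class TestFileRoundTrip:
    def test_written_files_reproduce_the_locus(self, tmp_path):
        """Parsing the emitted TSVs through the I/O layer and harmonizing
        gives the same locus as the in-memory shortcut."""
        cfg = SimConfig(seed=77, n_gwas=5_000, n_eqtl=5_000, n_ld=800)
        sc = simulate_scenario(cfg)
        sc.write(tmp_path)
        direct = sc.to_locus()

        gwas = read_summary_table(tmp_path / "gwas.tsv", "gwas")
        eqtl = read_summary_table(tmp_path / "eqtl.tsv", "eqtl")
        probes = read_probe_table(tmp_path / "probes.tsv")
        ld = load_ld_reference(tmp_path / "ld_corr.tsv", "correlation")
        loaded = harmonize_locus(probes[0], eqtl[probes[0].probe_id], gwas, ld)

        np.testing.assert_array_equal(loaded.snp_id, direct.snp_id)
        np.testing.assert_allclose(loaded.b_zx, direct.b_zx, rtol=1e-10)
        np.testing.assert_allclose(loaded.b_zy, direct.b_zy, rtol=1e-10)
        np.testing.assert_allclose(loaded.se_zy, direct.se_zy, rtol=1e-10)
        np.testing.assert_allclose(loaded.ld_r, direct.ld_r, rtol=1e-10)

        with open(tmp_path / "truth.json") as fh:
            truth = json.load(fh)
        assert truth["model"] == "pleiotropy"
        assert truth["causal_snp_id"] == sc.truth.causal_snp_id

    def test_underflowing_pvalue_survives_round_trip(self, tmp_path):
        """At study scale the causal SNP's p underflows past 1e-300; the
        generator must floor it above 0 so the reader keeps the row."""
        sc = simulate_scenario(SimConfig(seed=88))
        assert (sc.eqtl["p"] > 0).all()
        sc.write(tmp_path)
        eqtl = read_summary_table(tmp_path / "eqtl.tsv", "eqtl")
        kept = {v.snp_id for v in eqtl[sc.probe.probe_id]}
        assert sc.truth.causal_snp_id in kept
        assert len(kept) == len(sc.eqtl)

    def test_end_to_end_pleiotropy_is_retained(self):
        """A pleiotropic locus at study scale: instrument found, SMR small p,
        HEIDI retains (no heterogeneity)."""
        sc = simulate_scenario(SimConfig(seed=88, model="pleiotropy"))
        locus = sc.to_locus()
        top = select_top_instrument(locus)
        assert top is not None
        res = smr_test(locus)
        assert res.p_smr < 1e-4
        h = run_heidi(locus, top)
        assert h.status == "tested"
        assert h.p_heidi > 0.01

    def test_end_to_end_linkage_is_rejected(self):
        """A linkage locus at large n: SMR fires but HEIDI flags it."""
        sc = simulate_scenario(SimConfig(seed=89, model="linkage",
                                         n_gwas=50_000, n_eqtl=50_000))
        locus = sc.to_locus()
        top = select_top_instrument(locus)
        h = run_heidi(locus, top)
        assert h.status == "tested"
        assert h.p_heidi <= 0.01
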