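"""Shared fixtures: in-memory record builders and a multi-probe input set."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import block_diag

from mirsmr import (LDReference, ProbeRecord, SimConfig, VariantRecord,
                    simulate_scenario)


def make_variant(snp_id="rs1", chrom="1", bp=100, a1="A", a2="G", eaf=0.3,
                 beta=0.1, se=0.02, p=1e-6, n=10000.0) -> VariantRecord:
    return VariantRecord(snp_id=snp_id, chrom=chrom, bp=bp, effect_allele=a1,
                         other_allele=a2, eaf=eaf, beta=beta, se=se, p=p, n=n)


@pytest.fixture
def variant_factory():
    return make_variant


def build_multi_probe_inputs(n_probes: int, n_with_signal: int, seed: int,
                             n_samples: int = 4000, m_snps: int = 12):
    """Several independent cis loci on one chromosome, far enough apart that
    each probe's window sees only its own SNPs.  The first ``n_with_signal``
    probes carry a real eQTL effect; the rest have none (so no SNP reaches
    the instrument threshold at this sample size)."""
    gwas, eqtl, probes, lds, all_snps = [], {}, [], [], []
    for k in range(n_probes):
        b_zx = 0.35 if k < n_with_signal else 1e-6
        cfg = SimConfig(seed=seed * 1000 + k, model="pleiotropy",
                        n_gwas=n_samples, n_eqtl=n_samples, n_ld=1500,
                        m_snps=m_snps, b_zx=b_zx, b_zy=0.15)
        sc = simulate_scenario(cfg)
        offset = 10_000_000 * k
        rename = {old: f"p{k}_{old}" for old in sc.eqtl["snp"]}
        for df in (sc.eqtl, sc.gwas):
            df["snp"] = df["snp"].map(rename)
            df["bp"] = df["bp"] + offset
        probe = ProbeRecord(f"hsa-miR-sim-{k}", "1", sc.probe.tss_bp + offset)
        sc.eqtl["probe_id"] = probe.probe_id
        sc.eqtl["probe_tss"] = probe.tss_bp
        probes.append(probe)
        from mirsmr.sumstats import read_summary_table  # noqa: F401 (dialect)
        eq_records = [
            VariantRecord(r.snp, "1", int(r.bp), r.a1, r.a2, float(r.freq),
                          float(r.beta), float(r.se), float(max(r.p, 1e-300)),
                          float(r.n))
            for r in sc.eqtl.itertuples()]
        gw_records = [
            VariantRecord(r.snp, "1", int(r.bp), r.a1, r.a2, float(r.freq),
                          float(r.beta), float(r.se), float(max(r.p, 1e-300)),
                          float(r.n))
            for r in sc.gwas.itertuples()]
        eqtl[probe.probe_id] = eq_records
        gwas.extend(gw_records)
        lds.append(sc.ld.r)
        all_snps.extend(sc.eqtl["snp"].tolist())
    ld = LDReference(all_snps, block_diag(*lds))
    return gwas, eqtl, ld, probes


@pytest.fixture(scope="session")
def multi_probe_inputs():
    return build_multi_probe_inputs(n_probes=10, n_with_signal=4, seed=11)
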