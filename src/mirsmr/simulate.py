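"""Synthetic cis-locus and count-matrix generation.

Generates genotype dosages for an LD block (latent Gaussian AR(1) copula
thresholded to binomial(2, maf) dosages), paired GWAS / eQTL marginal
summary statistics under the three causal architectures relevant to
SMR-HEIDI —

* pleiotropy: one variant affects expression and trait directly,
* causality: the variant affects expression, which affects the trait,
* linkage:   two distinct LD-correlated variants affect expression and
  trait independently

— and negative-binomial miRNA count matrices for the differential-
expression stage.  GWAS, eQTL and LD-reference cohorts are drawn
independently, matching the non-overlapping-cohort assumption of the
analysis.  Marginal regressions use standardized genotypes by default so
effects are in per-SD units and the delta-method formulas apply directly;
``standardized=False`` emits per-allele effects instead.

All randomness flows from the mandatory per-config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .sumstats import HarmonizedLocus, LDReference, ProbeRecord

BLOCK_START_BP = 1_000_000
SNP_SPACING_BP = 1_000
MODELS = ("pleiotropy", "causality", "linkage")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cis-locus scenario.

    Defaults describe a well-powered single-probe locus: cohorts of 20,000
    (GWAS and eQTL) with a 2,000-sample LD reference panel, a 30-SNP block
    with strong AR(1) LD (rho = 0.8), MAFs uniform in [0.05, 0.5], a causal
    eQTL effect of 0.3 expression-SD per genotype-SD and a trait-side
    effect of 0.1 (pleiotropy/linkage) or b_xy = 0.3 (causality).
    """

    seed: int
    model: str = "pleiotropy"
    n_gwas: int = 20_000
    n_eqtl: int = 20_000
    n_ld: int = 2_000
    m_snps: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    rho: float = 0.8
    b_zx: float = 0.3
    b_zy: float = 0.1
    b_xy: float = 0.3
    linkage_r_target: float = 0.3
    linkage_r_tol: float = 0.05
    standardized: bool = True

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if min(self.n_gwas, self.n_eqtl, self.n_ld) < 2:
            raise ValueError("sample sizes must be >= 2")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.m_snps < 2:
            raise ValueError("need at least 2 SNPs in the block")
        if abs(self.b_zx) >= 1 or abs(self.b_zy) >= 1 or abs(self.b_xy) >= 1:
            raise ValueError("standardized effects must have magnitude < 1")


@dataclass(frozen=True)
class SimTruth:
    """What the generator actually did, for oracle checks."""

    model: str
    causal_index: int
    causal_snp_id: str
    second_index: int | None
    second_snp_id: str | None
    b_zx: float
    b_zy: float | None
    b_xy: float | None
    realized_ld: float | None
    seed: int


def simulate_genotypes(n: int, m: int, maf: np.ndarray | tuple[float, float],
                       rho: float, rng: np.random.Generator) -> np.ndarray:
    """Dosage matrix (n samples x m SNPs) with AR(1) latent LD structure.

    Each haplotype is a thresholded latent Gaussian AR(1) process across
    SNPs; the two haplotypes are independent, so dosages are binomial(2,
    maf) marginally and adjacent-SNP dosage correlation grows with rho.
    """
    if m < 2:
        raise ValueError("need at least 2 SNPs")
    maf = np.asarray(maf, dtype=float)
    if maf.size == 2 and maf.ndim == 1 and m != 2:
        maf = rng.uniform(maf[0], maf[1], size=m)
    elif maf.size != m:
        maf = rng.uniform(maf.min(), maf.max(), size=m)
    thresh = norm.ppf(maf)
    c = np.sqrt(1.0 - rho ** 2)
    dosage = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        z = rng.standard_normal((n, m))
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + c * z[:, j]
        dosage += z < thresh
    return dosage


def marginal_regression(genotypes: np.ndarray, y: np.ndarray,
                        standardized: bool = True):
    """Per-SNP simple least-squares of y on each genotype column.

    Returns (beta, se, p) arrays; with ``standardized`` the genotype is
    scaled to unit sample SD first, so beta is per genotype-SD.
    Monomorphic columns get beta 0, infinite se and p 1.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    G = np.asarray(genotypes, dtype=float)
    Gc = G - G.mean(axis=0)
    sg = Gc.std(axis=0)
    ok = sg > 0
    if standardized:
        Gc = np.divide(Gc, sg, out=Gc, where=ok)
    yc = y - y.mean()
    ss_g = (Gc ** 2).sum(axis=0)
    ss_y = float(yc @ yc)
    beta = np.zeros(G.shape[1])
    se = np.full(G.shape[1], np.inf)
    beta[ok] = (Gc[:, ok].T @ yc) / ss_g[ok]
    sse = np.maximum(ss_y - beta ** 2 * ss_g, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se[ok] = np.sqrt(sse[ok] / (n - 2) / ss_g[ok])
    se = np.maximum(se, 1e-300)
    # floor at the smallest positive double: p = 0 is not a valid p-value
    # and would be rejected by the summary-statistic reader on round-trip
    p = np.maximum(chi2.sf((beta / se) ** 2, df=1), np.nextafter(0.0, 1.0))
    p[~ok] = 1.0
    return beta, se, p


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


@dataclass
class Scenario:
    """A simulated locus: summary-statistic tables, LD reference and truth."""

    gwas: pd.DataFrame
    eqtl: pd.DataFrame
    ld: LDReference
    probe: ProbeRecord
    truth: SimTruth

    def to_locus(self) -> HarmonizedLocus:
        """Direct construction of the harmonized locus (alleles are already
        aligned by the generator; round-tripping through files gives the
        same result)."""
        eq, gw = self.eqtl, self.gwas
        return HarmonizedLocus(
            probe=self.probe,
            snp_id=eq["snp"].to_numpy(dtype=object),
            bp=eq["bp"].to_numpy(dtype=int),
            b_zx=eq["beta"].to_numpy(dtype=float),
            se_zx=eq["se"].to_numpy(dtype=float),
            p_zx=eq["p"].to_numpy(dtype=float),
            b_zy=gw["beta"].to_numpy(dtype=float),
            se_zy=gw["se"].to_numpy(dtype=float),
            p_zy=gw["p"].to_numpy(dtype=float),
            ld_r=self.ld.r.copy(),
            effect_allele=eq["a1"].to_numpy(dtype=object),
            other_allele=eq["a2"].to_numpy(dtype=object),
        )

    def write(self, outdir) -> None:
        """Write gwas.tsv, eqtl.tsv, ld_corr.tsv, probes.tsv and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gwas.to_csv(outdir / "gwas.tsv", sep="\t", index=False, na_rep="NA")
        self.eqtl.to_csv(outdir / "eqtl.tsv", sep="\t", index=False, na_rep="NA")
        ld_df = pd.DataFrame(self.ld.r, index=self.ld.snp_ids,
                             columns=self.ld.snp_ids)
        ld_df.to_csv(outdir / "ld_corr.tsv", sep="\t")
        pd.DataFrame([{"probe_id": self.probe.probe_id, "chr": self.probe.chrom,
                       "tss_bp": self.probe.tss_bp}]).to_csv(
            outdir / "probes.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(asdict(self.truth), fh, indent=1)


def _sumstat_frame(snp_ids, bps, dosage, beta, se, p, n) -> pd.DataFrame:
    return pd.DataFrame({
        "snp": snp_ids, "chr": "1", "bp": bps, "a1": "A", "a2": "G",
        "freq": dosage.mean(axis=0) / 2.0, "beta": beta, "se": se, "p": p,
        "n": n,
    })


def simulate_scenario(config: SimConfig,
                      genotypes: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
                      ) -> Scenario:
    """Simulate one cis-locus under the configured causal architecture.

    Expression in the eQTL cohort is x = b_zx * g_c(std) + noise of
    variance 1 - b_zx^2.  The trait follows the model: pleiotropy uses the
    same variant (y = b_zy * g_c + noise), causality regenerates x in the
    GWAS cohort and sets y = b_xy * x + noise, linkage picks a second
    variant whose LD-reference correlation with the causal one is within
    ``linkage_r_tol`` of ``linkage_r_target``.  Marginal per-SNP
    regressions in each cohort produce the summary statistics; the LD
    reference comes from a third independent cohort.

    Pass ``genotypes`` (eQTL, GWAS, LD dosage matrices) to hold the
    genotype draw fixed while resampling phenotypes.
    """
    rng = np.random.default_rng(config.seed)
    m = config.m_snps
    if genotypes is None:
        maf = rng.uniform(*config.maf_range, size=m)
        g_eqtl = simulate_genotypes(config.n_eqtl, m, maf, config.rho, rng)
        g_gwas = simulate_genotypes(config.n_gwas, m, maf, config.rho, rng)
        g_ld = simulate_genotypes(config.n_ld, m, maf, config.rho, rng)
    else:
        g_eqtl, g_gwas, g_ld = genotypes
        # keep the rng stream aligned regardless of how genotypes arrived
        rng = np.random.default_rng(rng.integers(2 ** 31))

    snp_ids = [f"snp{j:04d}" for j in range(m)]
    bps = BLOCK_START_BP + SNP_SPACING_BP * np.arange(m)
    causal = m // 2
    probe = ProbeRecord("hsa-miR-sim-5p", "1", int(bps[causal]))

    ld = LDReference.from_dosage(snp_ids, g_ld)

    # expression in the eQTL cohort
    x = config.b_zx * _standardize(g_eqtl[:, causal]) \
        + rng.normal(0.0, np.sqrt(1 - config.b_zx ** 2), config.n_eqtl)
    b_x, se_x, p_x = marginal_regression(g_eqtl, x, config.standardized)

    second = realized = None
    b_zy = b_xy = None
    if config.model == "pleiotropy":
        b_zy = config.b_zy
        y = b_zy * _standardize(g_gwas[:, causal]) \
            + rng.normal(0.0, np.sqrt(1 - b_zy ** 2), config.n_gwas)
    elif config.model == "causality":
        b_xy = config.b_xy
        x_gwas = config.b_zx * _standardize(g_gwas[:, causal]) \
            + rng.normal(0.0, np.sqrt(1 - config.b_zx ** 2), config.n_gwas)
        y = b_xy * x_gwas + rng.normal(0.0, np.sqrt(1 - b_xy ** 2), config.n_gwas)
    else:  # linkage
        b_zy = config.b_zy
        r_to_causal = ld.r[causal].copy()
        r_to_causal[causal] = np.inf  # never pick the causal SNP itself
        gap = np.abs(r_to_causal - config.linkage_r_target)
        second = int(np.argmin(gap))
        if gap[second] > config.linkage_r_tol:
            raise RuntimeError(
                f"no SNP with LD within {config.linkage_r_tol} of target "
                f"{config.linkage_r_target}; adjust rho or the block size")
        realized = float(ld.r[causal, second])
        y = b_zy * _standardize(g_gwas[:, second]) \
            + rng.normal(0.0, np.sqrt(1 - b_zy ** 2), config.n_gwas)
    b_y, se_y, p_y = marginal_regression(g_gwas, y, config.standardized)

    eqtl_df = _sumstat_frame(snp_ids, bps, g_eqtl, b_x, se_x, p_x, config.n_eqtl)
    eqtl_df["probe_id"] = probe.probe_id
    eqtl_df["probe_chr"] = probe.chrom
    eqtl_df["probe_tss"] = probe.tss_bp
    gwas_df = _sumstat_frame(snp_ids, bps, g_gwas, b_y, se_y, p_y, config.n_gwas)

    truth = SimTruth(
        model=config.model, causal_index=causal, causal_snp_id=snp_ids[causal],
        second_index=second,
        second_snp_id=None if second is None else snp_ids[second],
        b_zx=config.b_zx, b_zy=b_zy, b_xy=b_xy, realized_ld=realized,
        seed=config.seed)
    return Scenario(gwas=gwas_df, eqtl=eqtl_df, ld=ld, probe=probe, truth=truth)


def simulate_counts(n_mirnas: int, n_per_group: int, de_fraction: float,
                    fold: float, dispersion: float, seed: int,
                    mean_range: tuple[float, float] = (50.0, 1000.0),
                    mean: float | None = None):
    """Negative-binomial (gamma-mixed Poisson) tumor/normal count matrix.

    The first ``round(de_fraction * n_mirnas)`` miRNAs have their tumor
    mean multiplied by ``fold``; the rest are null.  Returns
    (counts DataFrame, condition labels, truth DataFrame with the
    generating fold per miRNA).
    """
    if fold <= 0 or dispersion <= 0:
        raise ValueError("fold and dispersion must be positive")
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    if mean is not None:
        base = np.full(n_mirnas, float(mean))
    else:
        base = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]),
                                  n_mirnas))
    n_de = int(round(de_fraction * n_mirnas))
    folds = np.ones(n_mirnas)
    folds[:n_de] = fold
    mu = np.concatenate([np.tile(base[:, None], (1, n_per_group)),
                         np.tile((base * folds)[:, None], (1, n_per_group))], axis=1)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    counts = rng.poisson(lam)
    samples = [f"normal_{i}" for i in range(n_per_group)] \
        + [f"tumor_{i}" for i in range(n_per_group)]
    condition = ["normal"] * n_per_group + ["tumor"] * n_per_group
    mirnas = [f"hsa-miR-sim-{i:04d}" for i in range(n_mirnas)]
    counts_df = pd.DataFrame(counts, index=mirnas, columns=samples)
    truth = pd.DataFrame({"mirna": mirnas, "fold": folds,
                          "is_de": folds != 1.0})
    return counts_df, condition, truth
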