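"""HEIDI: heterogeneity in dependent instruments.

A significant SMR association can arise from one variant affecting both
expression and trait (pleiotropy or causality) or from two distinct variants
in LD, one driving each (linkage).  Under the single-shared-variant model
every cis-SNP's Wald ratio b_xy(i) estimates the same quantity, so the
contrasts d_i = b_xy(i) - b_xy(top) are jointly zero in expectation.  HEIDI
standardizes the contrasts with a delta-method covariance that accounts for
LD between SNPs, sums their squares, and refers the sum to a weighted
chi-square null (eigenvalues of the contrast correlation matrix), by default
through the Satterthwaite two-moment approximation.  Associations with small
HEIDI p-values are flagged as linkage and discarded from the TWAS results.

The GWAS and eQTL cohorts are assumed non-overlapping, so cross-study
sampling covariance is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import chi2

from .sumstats import HarmonizedLocus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeidiConfig:
    """Tuning knobs of the HEIDI SNP selection and null approximation.

    Defaults follow standard SMR-HEIDI practice: cis-SNPs with eQTL
    p < 1.57e-3 (chi-square(1) > 10) and r^2 to the top SNP in
    [0.05, 0.9], at most 20 SNPs (smallest eQTL p kept), at least 3
    required to test.
    """

    p_zx_max: float = 1.57e-3
    r2_min: float = 0.05
    r2_max: float = 0.9
    m_cap: int = 20
    min_snps: int = 3
    method: str = "satterthwaite"  # or "imhof"
    use_reported_p: bool = False


@dataclass(frozen=True)
class HeidiResult:
    probe_id: str
    n_snps_used: int
    t_heidi: float | None
    p_heidi: float | None
    status: str  # tested | too_few_snps | skipped


def select_heidi_snps(locus: HarmonizedLocus, top: int,
                      config: HeidiConfig = HeidiConfig()) -> np.ndarray:
    """Indices of the SNPs entering the HEIDI test, in ascending-bp order.

    Always includes the top SNP (exempt from the r^2 window); other SNPs
    need eQTL p < p_zx_max and r^2 to the top in [r2_min, r2_max].  If more
    than m_cap qualify, the m_cap smallest eQTL p are kept.
    """
    from .smr import eqtl_pvalues

    m = locus.n_snps
    if m == 0:
        return np.array([], dtype=int)
    p = eqtl_pvalues(locus, use_reported_p=config.use_reported_p)
    r2 = locus.ld_r[:, top] ** 2
    elig = (p < config.p_zx_max) & (r2 >= config.r2_min) & (r2 <= config.r2_max)
    elig[top] = True
    idx = np.flatnonzero(elig)
    if len(idx) > config.m_cap:
        # keep the cap's worth of smallest eQTL p; the top SNP has the
        # locus-minimum p so it survives the cap by construction
        order = idx[np.argsort(p[idx], kind="stable")][:config.m_cap]
        if top not in order:
            order = np.concatenate([[top], order[:-1]])
        idx = np.sort(order)
    return idx


def bxy_covariance(locus: HarmonizedLocus, idx: np.ndarray) -> np.ndarray:
    """Delta-method sampling covariance of the per-SNP Wald ratios b_xy.

    With non-overlapping GWAS and eQTL cohorts,
    Cov(b_xy,i, b_xy,j) = r_ij se_zy,i se_zy,j / (b_zx,i b_zx,j)
                        + r_ij b_zy,i b_zy,j se_zx,i se_zx,j / (b_zx,i^2 b_zx,j^2)
    which reduces to the usual variance expression on the diagonal.
    """
    b_zx = locus.b_zx[idx]
    if np.any(b_zx == 0):
        raise ZeroDivisionError("b_zx is zero for a HEIDI SNP")
    b_zy = locus.b_zy[idx]
    se_zx = locus.se_zx[idx]
    se_zy = locus.se_zy[idx]
    r = locus.ld_r[np.ix_(idx, idx)]
    gwas_term = r * np.outer(se_zy, se_zy) / np.outer(b_zx, b_zx)
    eqtl_term = r * np.outer(b_zy * se_zx, b_zy * se_zx) / np.outer(b_zx ** 2, b_zx ** 2)
    cov = gwas_term + eqtl_term
    if np.any(np.diag(cov) <= 0):
        raise ValueError("non-positive b_xy variance; inputs look corrupt")
    return 0.5 * (cov + cov.T)


def heidi_statistic(locus: HarmonizedLocus, idx: np.ndarray, top: int,
                    cov: np.ndarray | None = None):
    """Heterogeneity statistic and standardized contrasts.

    d_i = b_xy(i) - b_xy(top) for each non-top selected SNP; the contrast
    covariance follows from the b_xy covariance; z_d,i = d_i / sd(d_i) and
    t_heidi = sum z_d,i^2.  Returns (t_heidi, z_d, corr_d) with corr_d the
    correlation matrix of the contrasts, which defines the null mixture.
    Contrasts with non-positive variance are dropped with a warning.
    """
    if cov is None:
        cov = bxy_covariance(locus, idx)
    pos = int(np.flatnonzero(idx == top)[0])
    b_xy = locus.b_zy[idx] / locus.b_zx[idx]
    d = np.delete(b_xy - b_xy[pos], pos)
    # Var(a - b) contrast rule applied to every pair of contrasts
    cov_d_full = cov - cov[:, [pos]] - cov[[pos], :] + cov[pos, pos]
    cov_d = np.delete(np.delete(cov_d_full, pos, axis=0), pos, axis=1)
    var_d = np.diag(cov_d).copy()
    good = var_d > 0
    if not good.all():
        logger.warning("dropping %d contrast(s) with non-positive variance",
                       int((~good).sum()))
        d = d[good]
        cov_d = cov_d[np.ix_(good, good)]
        var_d = var_d[good]
    if len(d) == 0:
        return 0.0, np.array([]), np.zeros((0, 0))
    sd = np.sqrt(var_d)
    z_d = d / sd
    corr_d = cov_d / np.outer(sd, sd)
    np.fill_diagonal(corr_d, 1.0)
    t_heidi = float(z_d @ z_d)
    return t_heidi, z_d, corr_d


def _imhof_pvalue(t: float, lam: np.ndarray) -> float:
    """Upper-tail probability of sum(lam_k chi^2_1) by Imhof's inversion integral."""

    def theta(u):
        return 0.5 * np.sum(np.arctan(np.multiply.outer(lam, u)), axis=0) - 0.5 * t * u

    def rho(u):
        return np.prod((1.0 + np.multiply.outer(lam ** 2, u ** 2)) ** 0.25, axis=0)

    def integrand(u):
        u = np.atleast_1d(u)
        return np.sin(theta(u)) / (u * rho(u))

    val, _ = integrate.quad(lambda u: float(integrand(u)[0]), 0, np.inf, limit=200)
    return float(np.clip(0.5 + val / np.pi, 1e-300, 1.0))


def heidi_pvalue(t_heidi: float, corr_d: np.ndarray,
                 method: str = "satterthwaite") -> float:
    """p-value of t_heidi against the weighted-chi-square null.

    Under the null the statistic is distributed as sum_k lambda_k chi^2_1
    with lambda_k the eigenvalues of the contrast correlation matrix
    (clipped at 0).  'satterthwaite' matches the first two moments with a
    scaled chi-square; 'imhof' inverts the characteristic function
    numerically.
    """
    corr_d = np.atleast_2d(np.asarray(corr_d, dtype=float))
    if corr_d.size == 0:
        logger.warning("no contrasts: p_heidi = 1")
        return 1.0
    lam = np.clip(np.linalg.eigvalsh(corr_d), 0.0, None)
    s1 = lam.sum()
    if s1 == 0:
        logger.warning("all null eigenvalues zero: p_heidi = 1")
        return 1.0
    if method == "imhof":
        if t_heidi <= 0:
            return 1.0
        return _imhof_pvalue(t_heidi, lam[lam > 1e-12])
    if method != "satterthwaite":
        raise ValueError(f"unknown HEIDI p-value method {method!r}")
    s2 = float(lam @ lam)
    scale = s2 / s1
    df = s1 ** 2 / s2
    return float(chi2.sf(t_heidi / scale, df=df))


def run_heidi(locus: HarmonizedLocus, top: int,
              config: HeidiConfig = HeidiConfig()) -> HeidiResult:
    """Full HEIDI test for one probe given its SMR instrument index.

    The retention decision (p_heidi > threshold) belongs to the pipeline;
    loci whose cis region offers fewer than ``min_snps`` eligible SNPs are
    reported as too_few_snps and left untested.
    """
    probe_id = locus.probe.probe_id
    idx = select_heidi_snps(locus, top, config)
    if len(idx) < config.min_snps:
        return HeidiResult(probe_id, int(len(idx)), None, None, "too_few_snps")
    cov = bxy_covariance(locus, idx)
    t, z_d, corr_d = heidi_statistic(locus, idx, top, cov)
    if len(z_d) == 0:
        return HeidiResult(probe_id, int(len(idx)), None, None, "too_few_snps")
    p = heidi_pvalue(t, corr_d, method=config.method)
    return HeidiResult(probe_id, int(len(idx)), t, p, "tested")
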