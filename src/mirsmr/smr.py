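"""The SMR (summary-data-based Mendelian randomization) test.

The test asks whether a trait association at a locus is mediated by gene
(here miRNA) expression, using the top cis-eQTL SNP as a single instrumental
variable.  With z_zx the eQTL z-statistic and z_zy the GWAS z-statistic at
that SNP, the test statistic is

    T_SMR = (z_zy^2 * z_zx^2) / (z_zy^2 + z_zx^2)

referred to a chi-square distribution with 1 degree of freedom.  The effect
of expression on the trait is the Wald ratio b_xy = b_zy / b_zx with a
first-order delta-method standard error.  The sign of b_xy is read
downstream as oncogenic (+) versus tumor-suppressive (-).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

from .sumstats import HarmonizedLocus, ProbeRecord, normalize_chrom

logger = logging.getLogger(__name__)

DEFAULT_P_INSTRUMENT_MAX = 5e-8

#: Extended MHC on GRCh37 (chr6), excluded because its extreme LD violates
#: the single-causal-variant assumption.  Closed interval, configurable.
MHC_REGION_GRCH37 = ("6", 28_477_797, 33_448_354)

# smallest positive subnormal double; p-values are floored here, never 0
_TINY = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class SmrTestOutput:
    """Per-probe SMR result at the selected instrument."""

    probe_id: str
    top_snp_id: str
    top_snp_bp: int
    b_xy: float
    se_xy: float
    t_smr: float
    p_smr: float


def smr_statistic(z_zx, z_zy):
    """T_SMR from the eQTL and GWAS z-statistics; symmetric in its arguments.

    Defined as 0 when both z are 0.  Bounded above by min(z_zx^2, z_zy^2).
    Accepts scalars or arrays.
    """
    z_zx = np.asarray(z_zx, dtype=float)
    z_zy = np.asarray(z_zy, dtype=float)
    denom = z_zx ** 2 + z_zy ** 2
    both_zero = denom == 0
    if np.any(both_zero):
        logger.warning("smr_statistic: both z-statistics zero; returning 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(both_zero, 0.0, (z_zy ** 2) * (z_zx ** 2) / np.where(both_zero, 1.0, denom))
    return float(t) if t.ndim == 0 else t


def smr_pvalue(t_smr, log: bool = False):
    """Upper-tail chi-square(1 df) p-value of T_SMR.

    Computed through the log survival function so extreme statistics stay
    finite; with ``log=False`` the result is floored at the smallest
    positive double rather than underflowing to 0.
    """
    t = np.asarray(t_smr, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_smr must be nonnegative")
    # chi-square(1) tail via the exact normal identity p = 2 Phi(-sqrt(t)),
    # which stays finite in log space far beyond where chi2.logsf underflows
    logp = np.log(2.0) + norm.logsf(np.sqrt(t))
    if log:
        return float(logp) if logp.ndim == 0 else logp
    p = np.maximum(np.exp(logp), _TINY)
    return float(p) if p.ndim == 0 else p


def estimate_bxy(b_zy, se_zy, b_zx, se_zx):
    """Wald-ratio effect of expression on trait with delta-method SE.

    b_xy = b_zy / b_zx;  se_xy^2 = se_zy^2/b_zx^2 + b_zy^2 se_zx^2 / b_zx^4.
    """
    b_zx = np.asarray(b_zx, dtype=float)
    if np.any(b_zx == 0):
        raise ZeroDivisionError("b_zx is zero: the Wald ratio is undefined")
    b_zy = np.asarray(b_zy, dtype=float)
    b_xy = b_zy / b_zx
    var = np.asarray(se_zy, dtype=float) ** 2 / b_zx ** 2 \
        + b_zy ** 2 * np.asarray(se_zx, dtype=float) ** 2 / b_zx ** 4
    se_xy = np.sqrt(var)
    if b_xy.ndim == 0:
        return float(b_xy), float(se_xy)
    return b_xy, se_xy


def eqtl_pvalues(locus: HarmonizedLocus, use_reported_p: bool = False) -> np.ndarray:
    """Per-SNP eQTL p-values, recomputed from beta/se unless told otherwise."""
    if use_reported_p:
        return np.asarray(locus.p_zx, dtype=float)
    return chi2.sf(locus.z_zx ** 2, df=1)


def check_pvalue_consistency(locus: HarmonizedLocus, rel_tol: float = 0.10) -> int:
    """Warn when reported p disagrees with beta/se by > rel_tol on the chi-square scale.

    Returns the number of discordant SNPs.
    """
    if locus.n_snps == 0:
        return 0
    chisq_from_beta = locus.z_zx ** 2
    with np.errstate(divide="ignore"):
        chisq_from_p = chi2.isf(np.clip(locus.p_zx, _TINY, 1.0), df=1)
    denom = np.maximum(chisq_from_beta, 1e-12)
    bad = np.abs(chisq_from_p - chisq_from_beta) / denom > rel_tol
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: %d SNP(s) with reported p inconsistent with beta/se",
                       locus.probe.probe_id, n_bad)
    return n_bad


def select_top_instrument(locus: HarmonizedLocus,
                          p_instrument_max: float = DEFAULT_P_INSTRUMENT_MAX,
                          use_reported_p: bool = False) -> int | None:
    """Index of the top cis-eQTL SNP, or None if no SNP reaches genome-wide significance.

    The instrument is the SNP with the smallest eQTL p-value below
    ``p_instrument_max`` (default 5e-8); ties are broken by larger |z_zx|,
    then smaller bp.  Probes without a qualifying instrument are excluded
    from the analysis.
    """
    if locus.n_snps == 0:
        return None
    p = eqtl_pvalues(locus, use_reported_p=use_reported_p)
    absz = np.abs(locus.z_zx)
    # lexicographic: smallest p, then largest |z|, then smallest bp (locus
    # order is bp-ascending, so stable argmin over (p, -|z|) suffices)
    order = np.lexsort((locus.bp, -absz, p))
    best = int(order[0])
    if p[best] >= p_instrument_max:
        return None
    return best


def smr_test(locus: HarmonizedLocus,
             p_instrument_max: float = DEFAULT_P_INSTRUMENT_MAX,
             use_reported_p: bool = False) -> SmrTestOutput | None:
    """Run the single-instrument SMR test for one probe.

    Returns None when no instrument qualifies.
    """
    top = select_top_instrument(locus, p_instrument_max, use_reported_p)
    if top is None:
        return None
    z_zx = locus.z_zx[top]
    z_zy = locus.z_zy[top]
    t = smr_statistic(z_zx, z_zy)
    b_xy, se_xy = estimate_bxy(locus.b_zy[top], locus.se_zy[top],
                               locus.b_zx[top], locus.se_zx[top])
    return SmrTestOutput(
        probe_id=locus.probe.probe_id,
        top_snp_id=str(locus.snp_id[top]),
        top_snp_bp=int(locus.bp[top]),
        b_xy=b_xy,
        se_xy=se_xy,
        t_smr=t,
        p_smr=smr_pvalue(t),
    )


def exclude_mhc(probe: ProbeRecord,
                mhc_region: tuple[str, int, int] = MHC_REGION_GRCH37) -> bool:
    """True iff the probe TSS lies inside the (closed) MHC interval."""
    chrom, lo, hi = mhc_region
    return normalize_chrom(probe.chrom) == normalize_chrom(chrom) \
        and lo <= probe.tss_bp <= hi
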