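"""Simplified tumor-vs-normal differential expression for miRNA counts.

A deliberately transparent negative-binomial Wald pipeline: median-of-ratios
size factors, per-miRNA method-of-moments dispersion (floored, no
empirical-Bayes shrinkage), an NB log-linear model with a tumor/normal
coefficient fitted by maximum likelihood at fixed dispersion, a two-sided
Wald test (referred to a t distribution with n - 2 degrees of freedom as a
small-sample correction for the estimated dispersion; this approaches the
usual normal reference as cohorts grow), and Benjamini-Hochberg FDR.  MA classification labels a miRNA
``up``/``down`` when fdr < alpha with a strictly positive/negative log2
fold change, ``ns`` otherwise.

The goal is correct NB Wald behavior under simulation, not bit-agreement
with any particular DE package: there is no dispersion shrinkage, outlier
replacement or independent filtering here.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pipeline import adjust_fdr

logger = logging.getLogger(__name__)

CONDITIONS = ("tumor", "normal")
DISPERSION_FLOOR = 1e-8
LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample (column).

    factor_s = median over genes g of counts[g, s] / geomean_g, using genes
    with all-positive counts; if none exist, falls back (with a warning) to
    per-gene geometric means over the positive entries only.
    """
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be nonnegative")
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        sub = mat[all_pos]
        log_geo = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geo[:, None]
    else:
        logger.warning("no gene positive in all samples; size factors use "
                       "positive entries only")
        with np.errstate(divide="ignore"):
            logs = np.where(mat > 0, np.log(mat), np.nan)
        log_geo = np.nanmean(logs, axis=1)
        usable = np.isfinite(log_geo)
        if not usable.any():
            raise ValueError("no expressed gene available for size factors")
        ratios = logs[usable] - log_geo[usable, None]
    with np.errstate(invalid="ignore"):
        factors = np.exp(np.nanmedian(ratios, axis=0))
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("could not compute positive size factors for all samples")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _validate_conditions(counts: pd.DataFrame, condition: Sequence[str]) -> np.ndarray:
    cond = np.asarray([str(c) for c in condition])
    if len(cond) != counts.shape[1]:
        raise ValueError("condition length does not match sample count")
    bad = set(cond) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    for label in CONDITIONS:
        if (cond == label).sum() < 2:
            raise ValueError(f"need >= 2 samples per condition, missing '{label}'")
    return cond


def _mom_dispersion(y: np.ndarray, sf: np.ndarray, tumor: np.ndarray) -> float:
    """Pooled within-condition method-of-moments NB dispersion on the
    normalized scale: Var = mu + alpha mu^2."""
    q = y / sf
    num = den = 0.0
    for grp in (tumor, ~tumor):
        qg = q[grp]
        mu = qg.mean()
        if mu <= 0 or len(qg) < 2:
            continue
        num += (qg.var(ddof=1) - mu) * len(qg)
        den += mu ** 2 * len(qg)
    if den == 0:
        return DISPERSION_FLOOR
    return max(num / den, DISPERSION_FLOOR)


def nb_wald_test(counts: pd.DataFrame, condition: Sequence[str],
                 alpha: float = 0.05) -> pd.DataFrame:
    """Per-miRNA negative-binomial Wald test of tumor vs normal.

    ``counts`` has miRNAs as rows and samples as columns; ``condition``
    labels each column 'tumor' or 'normal'.  Returns a DataFrame with
    columns mirna, base_mean, log2fc (tumor relative to normal),
    se_log2fc, p, fdr, ma_class.  All-zero miRNAs get missing statistics
    and class 'ns'.
    """
    cond = _validate_conditions(counts, condition)
    tumor = cond == "tumor"
    sf = size_factors(counts).to_numpy()
    mat = counts.to_numpy(dtype=float)
    base_mean = (mat / sf).mean(axis=1)
    design = sm.add_constant(tumor.astype(float))
    offset = np.log(sf)

    log2fc = np.full(len(counts), np.nan)
    se = np.full(len(counts), np.nan)
    pvals = np.full(len(counts), np.nan)
    for g in range(len(counts)):
        y = mat[g]
        if not y.any():
            continue
        disp = _mom_dispersion(y, sf, tumor)
        try:
            model = sm.GLM(y, design, offset=offset,
                           family=sm.families.NegativeBinomial(alpha=disp))
            fit = model.fit()
            coef, bse = fit.params[1], fit.bse[1]
            if not (np.isfinite(coef) and np.isfinite(bse) and bse > 0):
                raise ValueError("non-finite Wald components")
            log2fc[g] = coef / LN2
            se[g] = bse / LN2
            # t reference with n - 2 df absorbs dispersion-estimation noise
            pvals[g] = 2.0 * stats.t.sf(abs(coef / bse), df=mat.shape[1] - 2)
        except Exception as exc:  # noqa: BLE001 - degenerate genes stay untested
            logger.warning("NB fit failed for row %d (%s): %s",
                           g, counts.index[g], exc)

    fdr = np.full(len(counts), np.nan)
    tested = np.isfinite(pvals)
    if tested.any():
        fdr[tested] = adjust_fdr(np.clip(pvals[tested], np.nextafter(0, 1), 1.0))
    out = pd.DataFrame({
        "mirna": counts.index,
        "base_mean": base_mean,
        "log2fc": log2fc,
        "se_log2fc": se,
        "p": pvals,
        "fdr": fdr,
    })
    return ma_classify(out, alpha=alpha)


def ma_classify(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Attach the MA-plot class: up/down when fdr < alpha with a strictly
    signed log2fc, ns otherwise (including fdr exactly at alpha)."""
    df = results.copy()
    sig = (df["fdr"] < alpha) & np.isfinite(df["fdr"])
    cls = np.where(sig & (df["log2fc"] > 0), "up",
                   np.where(sig & (df["log2fc"] < 0), "down", "ns"))
    df["ma_class"] = cls
    n_up = int((cls == "up").sum())
    n_down = int((cls == "down").sum())
    logger.info("MA classes: %d up, %d down, %d ns", n_up, n_down,
                len(df) - n_up - n_down)
    return df


def ma_plot_data(results: pd.DataFrame) -> pd.DataFrame:
    """A (log2 mean), M (log2 fold change) and class, for external plotting."""
    with np.errstate(divide="ignore"):
        a = np.log2(results["base_mean"].to_numpy())
    return pd.DataFrame({"mirna": results["mirna"], "A": a,
                         "M": results["log2fc"], "class": results["ma_class"]})
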