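"""Per-probe orchestration: SMR -> BH-FDR -> HEIDI -> model/role calls.

One analysis run corresponds to one cancer (or GWAS subtype) paired with one
eQTL set.  FDR is controlled within the run, across exactly the probes that
had a qualifying instrument; HEIDI is computed only for FDR-significant
probes (configurable), and an association is declared significant when
fdr_smr < alpha AND p_heidi > heidi_threshold (the non-linkage call).  The
sign of b_xy among significant rows is read as the miRNA's predicted role:
negative = tumor-suppressive, positive = oncogenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import heidi as heidi_mod
from . import smr as smr_mod
from .heidi import HeidiConfig
from .sumstats import LDReference, ProbeRecord, VariantRecord, harmonize_locus

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "cancer", "probe", "chr", "bp", "topSNP", "b_SMR", "se_SMR", "p_SMR",
    "fdr_SMR", "p_HEIDI", "n_HEIDI_snps", "HEIDI_status", "model_call",
    "role_call", "significant",
]


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.  Monotone
    nondecreasing in p; an empty input yields an empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def classify_model(p_heidi: float | None, threshold: float = 0.01) -> str:
    """non_linkage if p_heidi > threshold, linkage if <= , untested if missing."""
    if p_heidi is None or (isinstance(p_heidi, float) and np.isnan(p_heidi)):
        return "untested"
    return "non_linkage" if p_heidi > threshold else "linkage"


def classify_role(b_xy: float) -> str:
    """Predicted miRNA role from the SMR effect sign."""
    if b_xy < 0:
        return "tumor_suppressive"
    if b_xy > 0:
        return "oncogenic"
    return "indeterminate"


@dataclass
class AnalysisConfig:
    """Configuration of one SMR-HEIDI run."""

    cancer_label: str = "trait"
    cis_window_bp: int = 1_000_000
    p_instrument_max: float = 5e-8
    fdr_alpha: float = 0.05
    heidi_threshold: float = 0.01
    heidi: HeidiConfig = field(default_factory=HeidiConfig)
    mhc_region: tuple[str, int, int] = smr_mod.MHC_REGION_GRCH37
    heidi_everywhere: bool = False
    use_reported_p: bool = False
    drop_ambiguous: bool = True
    resolve_by_eaf: bool = False
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        heidi_cfg = HeidiConfig(**raw.pop("heidi", {}))
        mhc = raw.pop("mhc_region", None)
        cfg = cls(heidi=heidi_cfg, **raw)
        if mhc is not None:
            cfg.mhc_region = (str(mhc[0]), int(mhc[1]), int(mhc[2]))
        return cfg


def run_analysis(gwas: Sequence[VariantRecord],
                 eqtl: Mapping[str, Sequence[VariantRecord]],
                 ld: LDReference,
                 probes: Iterable[ProbeRecord],
                 config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """One full SMR-HEIDI run over a probe set; returns the results table.

    Probes in the MHC or without a genome-wide-significant cis-eQTL
    instrument contribute no row; FDR is computed across the tested probes
    only.  The run is deterministic given inputs and config.
    """
    rows = []
    loci, tops = [], []
    n_mhc = n_no_instrument = n_empty = 0
    for probe in probes:
        if smr_mod.exclude_mhc(probe, config.mhc_region):
            n_mhc += 1
            logger.info("%s: excluded (MHC region)", probe.probe_id)
            continue
        locus = harmonize_locus(probe, eqtl.get(probe.probe_id, []), gwas, ld,
                                window=config.cis_window_bp,
                                drop_ambiguous=config.drop_ambiguous,
                                resolve_by_eaf=config.resolve_by_eaf)
        if locus.n_snps == 0:
            n_empty += 1
            logger.info("%s: excluded (empty harmonized locus)", probe.probe_id)
            continue
        top = smr_mod.select_top_instrument(locus, config.p_instrument_max,
                                            config.use_reported_p)
        if top is None:
            n_no_instrument += 1
            logger.info("%s: excluded (no cis-eQTL below p = %.3g)",
                        probe.probe_id, config.p_instrument_max)
            continue
        res = smr_mod.smr_test(locus, config.p_instrument_max, config.use_reported_p)
        rows.append({"probe": probe.probe_id, "chr": probe.chrom,
                     "bp": res.top_snp_bp, "topSNP": res.top_snp_id,
                     "b_SMR": res.b_xy, "se_SMR": res.se_xy, "p_SMR": res.p_smr})
        loci.append(locus)
        tops.append(top)
    if not rows:
        logger.warning("no testable probes in run '%s'", config.cancer_label)
        return pd.DataFrame(columns=RESULT_COLUMNS)

    df = pd.DataFrame(rows)
    df["fdr_SMR"] = adjust_fdr(df["p_SMR"].to_numpy())

    heidi_cfg = HeidiConfig(**{**config.heidi.__dict__,
                               "use_reported_p": config.use_reported_p})
    p_heidi, n_heidi, status = [], [], []
    for i, fdr in enumerate(df["fdr_SMR"].to_numpy()):
        if config.heidi_everywhere or fdr < config.fdr_alpha:
            hres = heidi_mod.run_heidi(loci[i], tops[i], heidi_cfg)
            p_heidi.append(np.nan if hres.p_heidi is None else hres.p_heidi)
            n_heidi.append(hres.n_snps_used)
            status.append(hres.status)
        else:
            p_heidi.append(np.nan)
            n_heidi.append(0)
            status.append("skipped")
    df["p_HEIDI"] = p_heidi
    df["n_HEIDI_snps"] = n_heidi
    df["HEIDI_status"] = status
    df["model_call"] = [classify_model(None if np.isnan(p) else p,
                                       config.heidi_threshold)
                        for p in df["p_HEIDI"]]
    df["role_call"] = [classify_role(b) for b in df["b_SMR"]]
    df["significant"] = (df["fdr_SMR"] < config.fdr_alpha) \
        & (df["model_call"] == "non_linkage")
    df["cancer"] = config.cancer_label
    df = df[RESULT_COLUMNS].copy()
    logger.info("run '%s': %d probes tested, %d FDR<%.2g, %d significant; "
                "excluded: %d MHC, %d no instrument, %d empty locus",
                config.cancer_label, len(df),
                int((df["fdr_SMR"] < config.fdr_alpha).sum()), config.fdr_alpha,
                int(df["significant"].sum()), n_mhc, n_no_instrument, n_empty)
    return df


def write_results(df: pd.DataFrame, path) -> None:
    """Write the results table as TSV with a fixed column order and formatting."""
    out = df[RESULT_COLUMNS] if all(c in df.columns for c in RESULT_COLUMNS) else df
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def overlap_across_runs(results: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """miRNAs significant in more than one run (e.g. a breast subtype and
    colorectal), reported as a probe x runs table."""
    combined = pd.concat(list(results), ignore_index=True)
    sig = combined[combined["significant"]]
    counts = sig.groupby("probe")["cancer"].agg(["nunique", lambda s: ",".join(sorted(s))])
    counts.columns = ["n_runs", "runs"]
    return counts[counts["n_runs"] > 1].reset_index()
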