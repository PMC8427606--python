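"""Reading, validation and allele harmonization of GWAS / cis-eQTL summary statistics.

The on-disk dialect is a COJO-``.ma``-like tab-separated table with columns
``snp chr bp a1 a2 freq beta se p n`` (``a1`` is the effect allele), plus
``probe_id probe_chr probe_tss`` for eQTL tables.  ``#``-prefixed lines are
comments and missing values are encoded ``NA``.  All effects are per copy of
the effect allele; harmonization rewrites every GWAS effect onto the eQTL
effect allele so that downstream ratio estimates share one sign convention.

Coordinates are 1-based GRCh37 throughout; the cis window is the closed
interval ``[tss - window, tss + window]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
#: A/T and C/G pairs cannot be oriented across strands without frequency info.
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

SUMSTAT_COLUMNS = ["snp", "chr", "bp", "a1", "a2", "freq", "beta", "se", "p", "n"]
EQTL_EXTRA_COLUMNS = ["probe_id", "probe_chr", "probe_tss"]
PROBE_COLUMNS = ["probe_id", "chr", "tss_bp"]

DEFAULT_CIS_WINDOW_BP = 1_000_000


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix and whitespace so '6' and 'chr6' compare equal."""
    return str(chrom).strip().removeprefix("chr")


@dataclass(frozen=True)
class VariantRecord:
    """One SNP's marginal summary statistics from a GWAS or eQTL study."""

    snp_id: str
    chrom: str
    bp: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    p: float
    n: float | None = None

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.snp_id}: p must be in (0, 1], got {self.p}")
        if self.bp < 1:
            raise ValueError(f"{self.snp_id}: bp must be >= 1, got {self.bp}")

    @property
    def z(self) -> float:
        return self.beta / self.se

    def flipped(self) -> "VariantRecord":
        """The same association expressed on the other allele."""
        return VariantRecord(
            snp_id=self.snp_id,
            chrom=self.chrom,
            bp=self.bp,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            beta=-self.beta,
            se=self.se,
            p=self.p,
            n=self.n,
        )


@dataclass(frozen=True)
class ProbeRecord:
    """A miRNA probe and the transcription start site anchoring its cis window."""

    probe_id: str
    chrom: str
    tss_bp: int

    def __post_init__(self):
        if self.tss_bp < 1:
            raise ValueError(f"{self.probe_id}: tss_bp must be >= 1")


class LDReference:
    """Pairwise genotype correlations for a SNP panel.

    Built either from a correlation matrix directly or from a dosage matrix
    (samples x SNPs, values in [0, 2]) by Pearson correlation of columns.
    """

    def __init__(self, snp_ids: Sequence[str], r: np.ndarray):
        r = np.asarray(r, dtype=float)
        if r.shape != (len(snp_ids), len(snp_ids)):
            raise ValueError("correlation matrix shape does not match snp_ids")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError("correlation matrix is not symmetric (tol 1e-8)")
        if not np.allclose(np.diag(r), 1.0, atol=1e-6):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.any(np.abs(r) > 1 + 1e-8):
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.snp_ids = list(snp_ids)
        self.r = 0.5 * (r + r.T)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def index_of(self, snp_id: str) -> int:
        return self._index[snp_id]

    def submatrix(self, snp_ids: Sequence[str]) -> np.ndarray:
        idx = [self._index[s] for s in snp_ids]
        return self.r[np.ix_(idx, idx)]

    @classmethod
    def from_dosage(cls, snp_ids: Sequence[str], dosage: np.ndarray) -> "LDReference":
        dosage = np.asarray(dosage, dtype=float)
        if dosage.ndim != 2 or dosage.shape[1] != len(snp_ids):
            raise ValueError("dosage must be samples x SNPs matching snp_ids")
        if np.nanmin(dosage) < 0 or np.nanmax(dosage) > 2:
            raise ValueError("dosage entries must lie in [0, 2]")
        sd = dosage.std(axis=0)
        keep = sd > 0
        if not keep.all():
            dropped = [s for s, k in zip(snp_ids, keep) if not k]
            logger.warning("excluding %d zero-variance SNP(s) from LD reference: %s",
                           len(dropped), dropped[:5])
        kept_ids = [s for s, k in zip(snp_ids, keep) if k]
        r = np.corrcoef(dosage[:, keep], rowvar=False)
        r = np.atleast_2d(r)
        np.fill_diagonal(r, 1.0)
        return cls(kept_ids, np.clip(r, -1.0, 1.0))


@dataclass
class HarmonizedLocus:
    """Allele-aligned eQTL + GWAS effects and LD for one probe's cis window.

    All arrays are parallel over the SNP intersection, sorted by ascending
    bp (ties broken by snp_id), and every beta pair refers to the eQTL
    effect allele.
    """

    probe: ProbeRecord
    snp_id: np.ndarray
    bp: np.ndarray
    b_zx: np.ndarray
    se_zx: np.ndarray
    p_zx: np.ndarray
    b_zy: np.ndarray
    se_zy: np.ndarray
    p_zy: np.ndarray
    ld_r: np.ndarray
    effect_allele: np.ndarray = field(default=None)
    other_allele: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.snp_id)
        for name in ("bp", "b_zx", "se_zx", "p_zx", "b_zy", "se_zy", "p_zy"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"array {name} length {len(arr)} != {n}")
        if self.ld_r.shape != (n, n):
            raise ValueError("ld_r shape does not match snp count")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    @property
    def z_zx(self) -> np.ndarray:
        return self.b_zx / self.se_zx

    @property
    def z_zy(self) -> np.ndarray:
        return self.b_zy / self.se_zy


def _empty_locus(probe: ProbeRecord) -> HarmonizedLocus:
    z = np.array([])
    return HarmonizedLocus(probe, np.array([], dtype=object), np.array([], dtype=int),
                           z, z, z, z, z, z, np.zeros((0, 0)),
                           np.array([], dtype=object), np.array([], dtype=object))


def is_ambiguous(a1: str, a2: str) -> bool:
    return (a1, a2) in AMBIGUOUS_PAIRS


def _records_from_frame(df: pd.DataFrame, path) -> list[VariantRecord]:
    records = []
    n_rejected = 0
    for row in df.itertuples():
        reason = None
        a1 = str(row.a1).upper().strip()
        a2 = str(row.a2).upper().strip()
        if pd.isna(row.beta) or pd.isna(row.se):
            reason = "non-numeric or missing beta/se"
        elif pd.isna(row.p) or pd.isna(row.bp):
            reason = "non-numeric or missing p/bp"
        elif a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
            reason = f"non-SNV alleles {a1}/{a2}"
        elif a1 == a2:
            reason = "identical alleles"
        elif row.se <= 0:
            reason = f"non-positive se {row.se}"
        elif not (0 < row.p <= 1):
            reason = f"p outside (0, 1]: {row.p}"
        elif row.bp < 1:
            reason = f"bp < 1: {row.bp}"
        if reason is not None:
            n_rejected += 1
            logger.warning("%s row %d (%s): rejected — %s", path, row.Index + 2,
                           getattr(row, "snp", "?"), reason)
            continue
        records.append(VariantRecord(
            snp_id=str(row.snp), chrom=normalize_chrom(row.chr), bp=int(row.bp),
            effect_allele=a1, other_allele=a2,
            eaf=None if pd.isna(row.freq) else float(row.freq),
            beta=float(row.beta), se=float(row.se), p=float(row.p),
            n=None if pd.isna(row.n) else float(row.n)))
    if n_rejected:
        logger.info("%s: %d row(s) rejected, %d retained", path, n_rejected, len(records))
    return records


def read_summary_table(path, kind: str):
    """Read a GWAS or eQTL summary-statistic TSV.

    Returns a list of :class:`VariantRecord` for ``kind='gwas'``; for
    ``kind='eqtl'`` a dict mapping probe_id to the probe's record list.
    Invalid rows are dropped with a logged reason; a missing mandatory
    column raises ``ValueError`` naming it.
    """
    if kind not in ("gwas", "eqtl"):
        raise ValueError(f"kind must be 'gwas' or 'eqtl', got {kind!r}")
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                     dtype={"snp": str, "chr": str, "a1": str, "a2": str})
    required = SUMSTAT_COLUMNS + (EQTL_EXTRA_COLUMNS if kind == "eqtl" else [])
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column '{col}'")
    for col in ("bp", "freq", "beta", "se", "p", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if kind == "gwas":
        return _records_from_frame(df, path)
    out: dict[str, list[VariantRecord]] = {}
    for probe_id, sub in df.groupby("probe_id", sort=True):
        out[str(probe_id)] = _records_from_frame(sub.reset_index(drop=True), path)
    return out


def read_probe_table(path) -> list[ProbeRecord]:
    """Read a probe annotation TSV with columns ``probe_id chr tss_bp``."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                     dtype={"probe_id": str, "chr": str})
    for col in PROBE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column '{col}'")
    return [ProbeRecord(str(r.probe_id), normalize_chrom(r.chr), int(r.tss_bp))
            for r in df.itertuples()]


def load_ld_reference(path, kind: str) -> LDReference:
    """Load an LD reference from a correlation-matrix or dosage TSV.

    ``ld_corr.tsv`` is a square matrix with SNP ids as header row and first
    column; ``dosage.tsv`` is samples x SNPs with SNP ids in the header.
    """
    if kind == "correlation":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: correlation matrix row/column ids differ")
        return LDReference([str(s) for s in df.columns], df.to_numpy(dtype=float))
    if kind == "dosage":
        df = pd.read_csv(path, sep="\t")
        return LDReference.from_dosage([str(s) for s in df.columns],
                                       df.to_numpy(dtype=float))
    raise ValueError(f"kind must be 'dosage' or 'correlation', got {kind!r}")


def _align_gwas_to_eqtl(eq: VariantRecord, gw: VariantRecord,
                        resolve_by_eaf: bool, eaf_margin: float):
    """Rewrite a GWAS record on the eQTL effect allele; None if incompatible."""
    e_pair = (eq.effect_allele, eq.other_allele)
    g_pair = (gw.effect_allele, gw.other_allele)
    if is_ambiguous(*e_pair) and resolve_by_eaf:
        # for A/T and C/G pairs the strand complement is the same letter
        # pair, so letters cannot orient the effect; use allele frequency
        if set(g_pair) != set(e_pair):
            return None
        if eq.eaf is None or gw.eaf is None:
            return None
        if abs(eq.eaf - 0.5) <= eaf_margin or abs(gw.eaf - 0.5) <= eaf_margin:
            return None
        eaf_gw_on_e1 = gw.eaf if gw.effect_allele == eq.effect_allele else 1 - gw.eaf
        same_side = (eq.eaf < 0.5) == (eaf_gw_on_e1 < 0.5)
        oriented = gw if gw.effect_allele == eq.effect_allele else gw.flipped()
        return oriented if same_side else oriented.flipped()
    if g_pair == e_pair:
        return gw
    if g_pair == e_pair[::-1]:
        return gw.flipped()
    return None


def harmonize_locus(probe: ProbeRecord,
                    eqtl: Iterable[VariantRecord],
                    gwas: Iterable[VariantRecord],
                    ld: LDReference,
                    window: int = DEFAULT_CIS_WINDOW_BP,
                    drop_ambiguous: bool = True,
                    resolve_by_eaf: bool = False,
                    eaf_margin: float = 0.08) -> HarmonizedLocus:
    """Intersect eQTL, GWAS and LD panels over one probe's cis window.

    SNPs are restricted to the closed window ``[tss - window, tss + window]``
    on the probe chromosome; GWAS effects are flipped onto the eQTL effect
    allele where the allele pair matches swapped; strand-ambiguous (A/T,
    C/G) SNPs are dropped unless ``resolve_by_eaf`` orients them by allele
    frequency (requiring ``|eaf - 0.5| > eaf_margin`` in both studies);
    allele-incompatible SNPs are dropped with a warning.  An empty
    intersection yields an empty locus, not an error.
    """
    chrom = normalize_chrom(probe.chrom)
    lo, hi = probe.tss_bp - window, probe.tss_bp + window
    eq_by_id: dict[str, VariantRecord] = {}
    any_on_chrom = False
    for rec in eqtl:
        if normalize_chrom(rec.chrom) != chrom:
            continue
        any_on_chrom = True
        if not (lo <= rec.bp <= hi):
            continue
        if rec.snp_id in eq_by_id:
            logger.warning("%s: duplicate eQTL row for %s; keeping first",
                           probe.probe_id, rec.snp_id)
            continue
        eq_by_id[rec.snp_id] = rec
    if not any_on_chrom:
        logger.warning("%s: no eQTL SNP on probe chromosome %s", probe.probe_id, chrom)
    gw_by_id: dict[str, VariantRecord] = {}
    for rec in gwas:
        if rec.snp_id in eq_by_id and rec.snp_id not in gw_by_id:
            gw_by_id[rec.snp_id] = rec

    keep: list[tuple[VariantRecord, VariantRecord]] = []
    for snp_id, eq in eq_by_id.items():
        if snp_id not in gw_by_id or snp_id not in ld:
            continue
        if is_ambiguous(eq.effect_allele, eq.other_allele) and drop_ambiguous \
                and not resolve_by_eaf:
            logger.debug("%s: dropping strand-ambiguous SNP %s", probe.probe_id, snp_id)
            continue
        aligned = _align_gwas_to_eqtl(eq, gw_by_id[snp_id], resolve_by_eaf, eaf_margin)
        if aligned is None:
            logger.warning("%s: dropping allele-incompatible SNP %s (%s/%s vs %s/%s)",
                           probe.probe_id, snp_id, eq.effect_allele, eq.other_allele,
                           gw_by_id[snp_id].effect_allele, gw_by_id[snp_id].other_allele)
            continue
        keep.append((eq, aligned))
    if not keep:
        return _empty_locus(probe)

    keep.sort(key=lambda pair: (pair[0].bp, pair[0].snp_id))
    eqs = [k[0] for k in keep]
    gws = [k[1] for k in keep]
    snp_ids = [e.snp_id for e in eqs]
    return HarmonizedLocus(
        probe=probe,
        snp_id=np.array(snp_ids, dtype=object),
        bp=np.array([e.bp for e in eqs], dtype=int),
        b_zx=np.array([e.beta for e in eqs]),
        se_zx=np.array([e.se for e in eqs]),
        p_zx=np.array([e.p for e in eqs]),
        b_zy=np.array([g.beta for g in gws]),
        se_zy=np.array([g.se for g in gws]),
        p_zy=np.array([g.p for g in gws]),
        ld_r=ld.submatrix(snp_ids),
        effect_allele=np.array([e.effect_allele for e in eqs], dtype=object),
        other_allele=np.array([e.other_allele for e in eqs], dtype=object),
    )
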