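"""Consensus filtering of miRNA target-gene predictions.

Three exported prediction tables are combined: miRDB (kept when
80 < score <= 100), TargetScan (kept when the cumulative weighted context
score <= -0.2, no lower bound) and miRTarBase (presence counts as
experimental evidence; all rows kept).  A gene is a consensus target of a
miRNA only when it survives all three source filters.  Gene symbols are
matched as upper-cased exact strings; aliasing is deliberately not
resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCES = ("mirdb", "targetscan", "mirtarbase")
MIRDB_MIN_EXCLUSIVE = 80.0
MIRDB_MAX = 100.0
TARGETSCAN_MAX = -0.2


@dataclass(frozen=True)
class ConsensusTarget:
    mirna_id: str
    gene_symbol: str
    mirdb_score: float
    targetscan_score: float


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["mirna"] = out["mirna"].astype(str).str.strip()
    out["gene"] = out["gene"].astype(str).str.strip().str.upper()
    return out


def read_target_table(path, source: str) -> pd.DataFrame:
    """Read one prediction export: TSV with columns ``mirna gene score``
    (score optional for miRTarBase)."""
    if source not in SOURCES:
        raise ValueError(f"source must be one of {SOURCES}, got {source!r}")
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    for col in ("mirna", "gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column '{col}'")
    if "score" not in df.columns:
        df["score"] = np.nan
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return _normalize(df[["mirna", "gene", "score"]])


def filter_source(rows: pd.DataFrame, source: str) -> pd.DataFrame:
    """Apply the per-database inclusion rule.

    miRDB: 80 < score <= 100 (strict lower, inclusive upper); TargetScan:
    score <= -0.2; miRTarBase: all rows kept.  Rows with out-of-range or
    missing scores where a score is required are rejected with a warning.
    """
    rows = _normalize(rows)
    if source == "mirdb":
        bad = rows["score"].isna() | (rows["score"] <= 0) | (rows["score"] > MIRDB_MAX)
        if bad.any():
            logger.warning("miRDB: rejecting %d row(s) with missing/out-of-range score",
                           int(bad.sum()))
        rows = rows[~bad]
        keep = (rows["score"] > MIRDB_MIN_EXCLUSIVE) & (rows["score"] <= MIRDB_MAX)
    elif source == "targetscan":
        bad = rows["score"].isna()
        if bad.any():
            logger.warning("TargetScan: rejecting %d row(s) without score",
                           int(bad.sum()))
        rows = rows[~bad]
        keep = rows["score"] <= TARGETSCAN_MAX
    elif source == "mirtarbase":
        keep = pd.Series(True, index=rows.index)
    else:
        raise ValueError(f"unknown source {source!r}")
    return rows[keep].drop_duplicates(subset=["mirna", "gene"]).reset_index(drop=True)


def intersect_targets(filtered: dict[str, pd.DataFrame],
                      mirna: str | None = None) -> list[ConsensusTarget]:
    """Genes present post-filter in all three sources for each miRNA.

    ``filtered`` maps source name to its filtered table.  Returns consensus
    targets sorted by (mirna, gene); an empty list is a valid outcome (some
    miRNAs have no gene shared by all three databases).
    """
    missing = set(SOURCES) - set(filtered)
    if missing:
        raise ValueError(f"missing filtered tables for: {sorted(missing)}")
    keys = {}
    for src in SOURCES:
        df = _normalize(filtered[src])
        if mirna is not None:
            df = df[df["mirna"] == mirna]
        keys[src] = df
    pair_sets = [set(zip(keys[s]["mirna"], keys[s]["gene"])) for s in SOURCES]
    common = set.intersection(*pair_sets)
    mirdb_scores = dict(zip(zip(keys["mirdb"]["mirna"], keys["mirdb"]["gene"]),
                            keys["mirdb"]["score"]))
    ts_scores = dict(zip(zip(keys["targetscan"]["mirna"], keys["targetscan"]["gene"]),
                         keys["targetscan"]["score"]))
    out = [ConsensusTarget(m, g, float(mirdb_scores[(m, g)]), float(ts_scores[(m, g)]))
           for m, g in sorted(common)]
    return out


def consensus_frame(targets: list[ConsensusTarget]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in targets],
                        columns=["mirna_id", "gene_symbol", "mirdb_score",
                                 "targetscan_score"])
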