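"""Worked-example fixture: the published 13 significant miRNA-cancer rows.

The packaged table carries the per-association SMR effect size, standard
error, FDR and HEIDI p-value as printed in the source study of
hormone-dependent cancers.  Re-scoring it through the pipeline's
classification stages (model call from p_heidi, role call from the effect
sign, the fdr < 0.05 AND p_heidi > 0.01 significance rule) is a fast
regression check that the filtering logic reproduces the published
discovery counts: 13 associations overall; 2 prostate, 5 breast (estrogen-
receptor subtypes counted with breast), 1 ovarian, 2 colorectal and 3
endometrial.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .pipeline import classify_model, classify_role

#: ER-status subtype runs are the same tissue; counts merge them into Breast.
_CANCER_GROUPS = {"Breast ER-": "Breast", "Breast ER+": "Breast"}


def load_table1() -> pd.DataFrame:
    """The packaged published-results table as a DataFrame."""
    with resources.files("mirsmr.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def score_table1(fdr_alpha: float = 0.05,
                 heidi_threshold: float = 0.01) -> pd.DataFrame:
    """Re-apply the model/role/significance calls to the published rows."""
    df = load_table1().copy()
    df["model_call"] = [classify_model(p, heidi_threshold) for p in df["p_heidi"]]
    df["role_call"] = [classify_role(b) for b in df["b_smr"]]
    df["significant"] = (df["fdr_smr"] < fdr_alpha) & (df["model_call"] == "non_linkage")
    df["cancer_group"] = df["cancer"].replace(_CANCER_GROUPS)
    return df


def significant_counts_by_cancer(scored: pd.DataFrame | None = None) -> dict[str, int]:
    """Significant-association counts per cancer, ER subtypes merged into breast."""
    if scored is None:
        scored = score_table1()
    sig = scored[scored["significant"]]
    return sig.groupby("cancer_group").size().to_dict()
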