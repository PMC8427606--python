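"""Worked example 4: triple-database consensus filtering of target genes.

A gene counts as a consensus target of a miRNA only when it passes all
three source filters: miRDB score in (80, 100], TargetScan cumulative
weighted context score <= -0.2, and presence in miRTarBase.
"""

import pandas as pd

from mirsmr import filter_source, intersect_targets
from mirsmr.targets import consensus_frame

mir = "hsa-miR-204-5p"

mirdb = pd.DataFrame({"mirna": mir,
                      "gene": ["SHC4", "BCL2", "EZR", "TGFBR2"],
                      "score": [95.0, 88.0, 80.0, 72.0]})   # EZR at 80 fails
targetscan = pd.DataFrame({"mirna": mir,
                           "gene": ["SHC4", "BCL2", "SOX4"],
                           "score": [-0.45, -0.20, -0.31]})  # -0.2 passes
mirtarbase = pd.DataFrame({"mirna": mir,
                           "gene": ["SHC4", "BCL2", "SOX4", "EZR"]})
mirtarbase["score"] = float("nan")

filtered = {"mirdb": filter_source(mirdb, "mirdb"),
            "targetscan": filter_source(targetscan, "targetscan"),
            "mirtarbase": filter_source(mirtarbase, "mirtarbase")}
for src, df in filtered.items():
    print(f"{src}: {sorted(df['gene'])}")

consensus = intersect_targets(filtered)
print("\nconsensus targets (present in all three):")
print(consensus_frame(consensus).to_string(index=False))
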