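"""Sex- and therapy-stratified detection plus the between-stratum volcano.

For PTs signal-positive in both strata, the between-stratum ROR (female vs
male, monotherapy vs combination) is tested with a 1-df chi-square and
BH-adjusted; direction A means more reported in females / without
co-medication.
"""

import pandas as pd

from _common import OUT_DIR, run_config
from faerspv.pipeline import run_pipeline

run_pipeline(run_config(), ["subgroup"])
for name in ("sex", "therapy"):
    df = pd.read_csv(OUT_DIR / f"volcano_{name}.tsv", sep="\t")
    print(f"-- {name} comparison ({len(df)} shared positive PTs)")
    if len(df):
        cols = ["pt", "ror", "p_adj", "log2_ror", "neg_log10_padj", "direction"]
        print(df[cols].round(4).to_string(index=False))
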