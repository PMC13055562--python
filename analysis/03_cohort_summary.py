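"""Descriptive tables: demographics, therapy split, worst outcomes, yearly counts."""

import pandas as pd

from _common import OUT_DIR, run_config
from faerspv.pipeline import run_pipeline

run_pipeline(run_config(), ["summarize"])
for name in ("sex", "age", "therapy", "worst_outcome"):
    df = pd.read_csv(OUT_DIR / f"summary_{name}.tsv", sep="\t")
    print(f"-- {name}")
    print(df.to_string(index=False))
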