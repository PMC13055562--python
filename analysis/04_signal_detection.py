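"""PT- and SOC-level disproportionality detection with the joint criteria.

A PT (or SOC) is a signal when ROR025 > 1, PRR > 2, chi2 > 4, a >= 3 and
IC025 > 0 all hold.  The elevated PTs injected by the generator should be
flagged; the null PTs should not.
"""

import pandas as pd

from _common import OUT_DIR, run_config
from faerspv.pipeline import run_pipeline

run_pipeline(run_config(), ["detect"])
for level in ("pt", "soc"):
    df = pd.read_csv(OUT_DIR / f"signals_{level}.tsv", sep="\t")
    pos = df[df.signal_positive]
    print(f"-- {level.upper()} level: {len(pos)} signal(s) of {len(df)} labels")
    cols = ["label", "a", "ror", "ror025", "prr", "chi2", "ic025"]
    print(pos[cols].round(2).to_string(index=False))
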