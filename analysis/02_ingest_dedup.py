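"""Parse the extract, deduplicate case versions, select the drug cohort.

Applies the recency rule (latest FDA receipt date per case, ties to the
larger PRIMARYID) and splits deduplicated reports into the target-drug
cohort (primary suspect + qualifying indication) and the full-database
background comparator.
"""

import pandas as pd

from _common import OUT_DIR, run_config
from faerspv.pipeline import run_pipeline

run_pipeline(run_config(), ["ingest"])
audit = pd.read_csv(OUT_DIR / "ingest_audit.tsv", sep="\t")
row = audit.iloc[0]
print(f"deduplicated cases: {row.n_cases} (removed {row.n_removed_duplicates} versions)")
print(f"cohort: {row.n_cohort}  background: {row.n_background}")
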