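"""Shared configuration for the numbered analysis drivers.

Every driver reads/writes under results/study and uses one seed, so the
whole sequence is reproducible with `for s in analysis/0*.py; do python $s; done`.
"""

from pathlib import Path

from faerspv.pipeline import RunConfig
from faerspv.synthetic import GeneratorConfig

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "study" / "data"
OUT_DIR = ROOT / "results" / "study"
SEED = 7
N_REPORTS = 60_000


def run_config() -> RunConfig:
    return RunConfig(
        input_dir=DATA_DIR,
        output_dir=OUT_DIR,
        seed=SEED,
        generator=GeneratorConfig(n_reports=N_REPORTS, seed=SEED),
    )
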