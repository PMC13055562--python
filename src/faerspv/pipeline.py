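"""Deterministic end-to-end orchestration of the study stages.

Stage order: simulate -> ingest -> {summarize, detect, subgroup, tto}.  Each
stage reads the previous stage's on-disk artifacts, so stages can run in
separate invocations; a missing upstream artifact raises
:class:`DependencyError` naming the stage.  Every output table is TSV and
gets a manifest line (stage, input hash, row count); identical config and
inputs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from faerspv import cohort as cohort_mod
from faerspv import signals, subgroups, synthetic, tto
from faerspv.ingest import ReportCase, parse_tables, split_cohort
from faerspv.vocab import DEFAULT_INDICATIONS, DEFAULT_SYNONYMS, PT_SOC

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ingest", "summarize", "detect", "subgroup", "tto")


class ValidationError(ValueError):
    """Bad configuration or inputs (CLI exit code 2)."""


class DependencyError(RuntimeError):
    """A required upstream artifact is missing (CLI exit code 3)."""


@dataclass
class RunConfig:
    input_dir: Path
    output_dir: Path
    synonym_file: Path | None = None
    indication_file: Path | None = None
    pt_soc_file: Path | None = None
    seed: int = 0
    generator: synthetic.GeneratorConfig | None = None
    indication_any_drug: bool = False

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)

    def synonyms(self) -> list[str]:
        if self.synonym_file:
            return _read_terms(self.synonym_file)
        return list(DEFAULT_SYNONYMS)

    def indications(self) -> list[str]:
        if self.indication_file:
            return _read_terms(self.indication_file)
        return list(DEFAULT_INDICATIONS)

    def pt_soc_map(self) -> dict[str, str]:
        path = self.pt_soc_file or (self.input_dir / "pt_soc_map.tsv")
        if Path(path).exists():
            return signals.load_pt_soc_map(path)
        return {k.casefold(): v for k, v in PT_SOC.items()}


def _read_terms(path: str | Path) -> list[str]:
    terms = [ln.strip() for ln in Path(path).read_text().splitlines()]
    terms = [t for t in terms if t and not t.startswith("#")]
    if not terms:
        raise ValidationError(f"term file {path} is empty")
    return terms


def _hash_files(paths: Sequence[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(p) for p in paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


_LIST_SEP = "|"


def _pack_cases(cases: Sequence[ReportCase]) -> pd.DataFrame:
    rows = []
    for c in cases:
        rows.append(
            {
                "caseid": c.caseid,
                "primaryid": c.primaryid,
                "fda_dt": c.fda_dt.strftime("%Y%m%d") if c.fda_dt else "",
                "event_dt": c.event_dt_raw,
                "sex": c.sex,
                "age_years": "" if c.age_years is None else f"{c.age_years:.6g}",
                "weight_kg": "" if c.weight_kg is None else f"{c.weight_kg:.6g}",
                "occupation": c.occupation,
                "country": c.country,
                "drugs": _LIST_SEP.join(f"{s}:{r}:{n}" for s, n, r in c.drugs),
                "pts": _LIST_SEP.join(c.pts),
                "outcomes": _LIST_SEP.join(c.outcomes),
                "therapy_starts": _LIST_SEP.join(f"{s}:{d}" for s, d in c.therapy_starts),
                "indications": _LIST_SEP.join(f"{s}:{p}" for s, p in c.indications),
            }
        )
    return pd.DataFrame(rows)


def _unpack_cases(df: pd.DataFrame) -> list[ReportCase]:
    from faerspv.ingest import parse_date8

    cases = []
    for r in df.itertuples(index=False):
        d = r._asdict()

        def _split(s: str) -> list[str]:
            s = "" if pd.isna(s) else str(s)
            return [x for x in s.split(_LIST_SEP) if x]

        drugs = []
        for item in _split(d["drugs"]):
            seq, role, name = item.split(":", 2)
            drugs.append((int(seq), name, role))
        cases.append(
            ReportCase(
                caseid=int(d["caseid"]),
                primaryid=int(d["primaryid"]),
                fda_dt=parse_date8(d["fda_dt"]),
                event_dt_raw="" if pd.isna(d["event_dt"]) else str(d["event_dt"]),
                sex="" if pd.isna(d["sex"]) else str(d["sex"]),
                age_years=None if str(d["age_years"]) in ("", "nan") else float(d["age_years"]),
                weight_kg=None if str(d["weight_kg"]) in ("", "nan") else float(d["weight_kg"]),
                occupation="" if pd.isna(d["occupation"]) else str(d["occupation"]),
                country="" if pd.isna(d["country"]) else str(d["country"]),
                drugs=drugs,
                pts=_split(d["pts"]),
                outcomes=_split(d["outcomes"]),
                therapy_starts=[
                    (int(x.split(":", 1)[0]), x.split(":", 1)[1]) for x in _split(d["therapy_starts"])
                ],
                indications=[
                    (int(x.split(":", 1)[0]), x.split(":", 1)[1]) for x in _split(d["indications"])
                ],
            )
        )
    return cases


def _load_cases(path: Path, stage: str) -> list[ReportCase]:
    if not path.exists():
        raise DependencyError(
            f"stage '{stage}' needs {path.name}; run the 'ingest' stage first"
        )
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return _unpack_cases(df)


def run_pipeline(config: RunConfig, stages: Sequence[str] = STAGES) -> list[dict]:
    """Run the requested stages in dependency order; return the manifest rows."""
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stage(s): {unknown}")
    ordered = [s for s in STAGES if s in set(stages)]
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(stage: str, artifact: Path, input_hash: str, rows: int) -> None:
        manifest.append(
            {
                "stage": stage,
                "artifact": str(artifact.relative_to(out)),
                "input_hash": input_hash,
                "rows": rows,
            }
        )

    for stage in ordered:
        t0 = time.perf_counter()
        if stage == "simulate":
            gen = config.generator or synthetic.GeneratorConfig(seed=config.seed)
            paths, _ = synthetic.generate_extract(gen, config.input_dir)
            # simulate artifacts live under input_dir (they feed ingest)
            for p in paths.values():
                rows = 1 if p.suffix == ".json" else max(0, sum(1 for _ in open(p)) - 1)
                manifest.append(
                    {"stage": stage, "artifact": str(p), "input_hash": "-", "rows": rows}
                )
        elif stage == "ingest":
            files = sorted(config.input_dir.glob("*.txt"))
            if not files:
                raise DependencyError(
                    f"stage 'ingest' found no quarterly tables in {config.input_dir}; "
                    "run 'simulate' or point input_dir at an extract"
                )
            ih = _hash_files(files)
            result = parse_tables(files)
            cohort, background = split_cohort(
                result.cases,
                config.synonyms(),
                config.indications(),
                config.indication_any_drug,
            )
            for name, cases in (("cohort", cohort), ("background", background)):
                path = out / f"{name}_cases.tsv"
                _write_tsv(_pack_cases(cases), path)
                record(stage, path, ih, len(cases))
            audit = pd.DataFrame(
                [
                    {
                        "n_cases": len(result.cases),
                        "n_cohort": len(cohort),
                        "n_background": len(background),
                        "n_removed_duplicates": len(result.removed_primaryids),
                        **{f"malformed_{k}": v for k, v in result.malformed_rows.items()},
                    }
                ]
            )
            path = out / "ingest_audit.tsv"
            _write_tsv(audit, path)
            record(stage, path, ih, 1)
            pd.DataFrame({"primaryid": result.removed_primaryids}).pipe(
                _write_tsv, out / "removed_primaryids.tsv"
            )
            record(stage, out / "removed_primaryids.tsv", ih, len(result.removed_primaryids))
        elif stage == "summarize":
            cohort = _load_cases(out / "cohort_cases.tsv", stage)
            if not cohort:
                raise ValidationError("cohort is empty; nothing to summarize")
            ih = _hash_files([out / "cohort_cases.tsv"])
            summary = cohort_mod.summarize(cohort, config.synonyms())
            for name, df in summary.tables.items():
                path = out / f"summary_{name}.tsv"
                _write_tsv(df, path)
                record(stage, path, ih, len(df))
            path = out / "summary_yearly.tsv"
            _write_tsv(summary.yearly, path)
            record(stage, path, ih, len(summary.yearly))
        elif stage == "detect":
            cohort = _load_cases(out / "cohort_cases.tsv", stage)
            background = _load_cases(out / "background_cases.tsv", stage)
            ih = _hash_files([out / "cohort_cases.tsv", out / "background_cases.tsv"])
            for level in ("pt", "soc"):
                results, unmapped = signals.detect(
                    cohort,
                    background,
                    level=level,
                    pt_to_soc=config.pt_soc_map() if level == "soc" else None,
                )
                path = out / f"signals_{level}.tsv"
                _write_tsv(signals.results_table(results), path)
                record(stage, path, ih, len(results))
                if unmapped:
                    upath = out / "unmapped_pts.tsv"
                    _write_tsv(pd.DataFrame({"pt": sorted(unmapped)}), upath)
                    record(stage, upath, ih, len(unmapped))
        elif stage == "subgroup":
            cohort = _load_cases(out / "cohort_cases.tsv", stage)
            background = _load_cases(out / "background_cases.tsv", stage)
            ih = _hash_files([out / "cohort_cases.tsv", out / "background_cases.tsv"])
            strata = {
                "sex": (
                    subgroups.sex_stratum("F"),
                    subgroups.sex_stratum("M"),
                    lambda c: c.sex in ("F", "M"),
                ),
                "therapy": (
                    subgroups.therapy_stratum("monotherapy", config.synonyms()),
                    subgroups.therapy_stratum("combination", config.synonyms()),
                    lambda c: True,
                ),
            }
            for name, (pred_a, pred_b, _) in strata.items():
                res_a, _ = subgroups.stratified_detect(cohort, background, pred_a)
                res_b, _ = subgroups.stratified_detect(cohort, background, pred_b)
                for tag, res in (("a", res_a), ("b", res_b)):
                    path = out / f"signals_{name}_{tag}.tsv"
                    _write_tsv(signals.results_table(res), path)
                    record(stage, path, ih, len(res))
                shared = subgroups.shared_positive_pts(res_a, res_b)
                cohort_a = [c for c in cohort if pred_a(c)]
                cohort_b = [c for c in cohort if pred_b(c)]
                if shared and cohort_a and cohort_b:
                    comparisons = subgroups.compare_strata(shared, cohort_a, cohort_b)
                    vol = subgroups.volcano_table(comparisons)
                else:
                    vol = subgroups.volcano_table([])
                path = out / f"volcano_{name}.tsv"
                _write_tsv(vol, path)
                record(stage, path, ih, len(vol))
        elif stage == "tto":
            cohort = _load_cases(out / "cohort_cases.tsv", stage)
            ih = _hash_files([out / "cohort_cases.tsv"])
            records, exclusions = tto.compute_tto(cohort, config.synonyms())
            path = out / "tto_records.tsv"
            _write_tsv(tto.tto_table(records), path)
            record(stage, path, ih, len(records))
            _write_tsv(
                pd.DataFrame([exclusions]), out / "tto_exclusions.tsv"
            )
            record(stage, out / "tto_exclusions.tsv", ih, 1)
            if len(records) >= tto.MIN_FIT_N:
                fit = tto.weibull_fit([r.onset_days for r in records])
                path = out / "tto_weibull.tsv"
                _write_tsv(tto.fit_summary_table(fit), path)
                record(stage, path, ih, 1)
            sexes = {r.sex for r in records if r.sex in ("F", "M")}
            if len(sexes) == 2:
                stat, p, curve = tto.logrank_by_sex(records)
                _write_tsv(
                    pd.DataFrame([{"statistic": stat, "p": p}]), out / "tto_logrank.tsv"
                )
                record(stage, out / "tto_logrank.tsv", ih, 1)
                _write_tsv(curve, out / "tto_cumulative_incidence.tsv")
                record(stage, out / "tto_cumulative_incidence.tsv", ih, len(curve))
        logger.info("stage %-9s done in %.2fs", stage, time.perf_counter() - t0)

    mpath = out / "manifest.tsv"
    _write_tsv(pd.DataFrame(manifest), mpath)
    return manifest
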