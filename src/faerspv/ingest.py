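"""Quarterly-extract ingestion: parsing, deduplication, cohort selection.

FAERS-style extracts arrive as "$"-delimited ASCII tables (DEMO, DRUG, REAC,
OUTC, THER, INDI) keyed by PRIMARYID (one report version) and CASEID (one
case).  Cases accumulate versions over time, so the first analysis step is
the FDA deduplication rule: keep, per CASEID, the version with the most
recent FDA receipt date, breaking ties by the larger PRIMARYID.  The cohort
is then the set of deduplicated cases naming the target drug as primary
suspect (role PS) with a qualifying indication; everything else is the
disproportionality background.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from faerspv.vocab import DEFAULT_INDICATIONS, DEFAULT_SYNONYMS, normalize_name

logger = logging.getLogger(__name__)

_DATE8 = re.compile(r"^\d{8}$")

TABLE_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "fda_dt", "event_dt", "sex"],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
}

ROLE_CODES = {"PS", "SS", "C", "I"}
OUTCOME_SEVERITY = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

_AGE_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

LB_TO_KG = 0.45359237


class FormatError(ValueError):
    """A table is structurally unusable (e.g. a mandatory column is absent)."""


def parse_date8(value: str | None) -> dt.date | None:
    """Parse a strict 8-digit YYYYMMDD value; anything else is missing.

    FAERS date fields may carry 4- or 6-digit partial dates; the study's
    cleaning rule treats those as incomplete, so only full-precision dates
    are ever used (deduplication and time-to-onset alike).
    """
    if value is None:
        return None
    s = str(value).strip()
    if not _DATE8.match(s):
        return None
    try:
        return dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None


@dataclass
class ReportCase:
    """One deduplicated safety report."""

    caseid: int
    primaryid: int
    fda_dt: dt.date | None = None
    event_dt_raw: str = ""
    sex: str = ""
    age_years: float | None = None
    weight_kg: float | None = None
    occupation: str = ""
    country: str = ""
    drugs: list[tuple[int, str, str]] = field(default_factory=list)  # (seq, name, role)
    pts: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)
    therapy_starts: list[tuple[int, str]] = field(default_factory=list)  # (drug_seq, raw)
    indications: list[tuple[int, str]] = field(default_factory=list)  # (drug_seq, pt)

    @property
    def receipt_year(self) -> int | None:
        return self.fda_dt.year if self.fda_dt else None

    def drug_seqs_matching(self, synonyms_norm: frozenset[str]) -> list[int]:
        return [seq for seq, name, _ in self.drugs if normalize_name(name) in synonyms_norm]

    def has_target_ps(self, synonyms_norm: frozenset[str]) -> bool:
        return any(
            role == "PS" and normalize_name(name) in synonyms_norm
            for _, name, role in self.drugs
        )


@dataclass
class IngestResult:
    """Parsed, deduplicated cases plus an audit trail of what was dropped."""

    cases: list[ReportCase]
    removed_primaryids: list[int]
    malformed_rows: dict[str, int]
    table_rows: dict[str, int]

    def __iter__(self) -> Iterator[ReportCase]:
        return iter(self.cases)

    def __len__(self) -> int:
        return len(self.cases)


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per CASEID: latest FDA_DT, ties broken by larger PRIMARYID.

    ``records`` needs columns ``caseid``, ``primaryid`` and ``fda_dt`` (raw
    string; non-8-digit values count as missing and rank below every real
    date, so a dated version always supersedes an undated one).  Row order
    never affects the outcome.
    """
    if records.empty:
        return records.copy()
    df = records.copy()
    fda_key = df["fda_dt"].astype(str).where(
        df["fda_dt"].astype(str).str.fullmatch(r"\d{8}"), ""
    )
    df["_fda_key"] = fda_key.fillna("")
    df["_pid_key"] = pd.to_numeric(df["primaryid"])
    df = df.sort_values(["caseid", "_fda_key", "_pid_key"], kind="stable")
    kept = df.drop_duplicates("caseid", keep="last").drop(columns=["_fda_key", "_pid_key"])
    return kept.sort_index()


def _read_table(path: Path, table: str) -> tuple[pd.DataFrame, int]:
    bad = 0

    def _on_bad(line: list[str]) -> None:
        nonlocal bad
        bad += 1
        return None

    df = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        keep_default_na=False,
        engine="python",
        on_bad_lines=_on_bad,
    )
    missing = [c for c in TABLE_COLUMNS[table] if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing mandatory column(s) {missing} for {table}")
    if bad:
        logger.warning("%s: %d malformed row(s) skipped", path.name, bad)
    return df, bad


def _classify_files(paths: Iterable[str | Path]) -> dict[str, list[Path]]:
    grouped: dict[str, list[Path]] = {t: [] for t in TABLE_COLUMNS}
    for p in paths:
        p = Path(p)
        stem = p.name.upper()
        for table in TABLE_COLUMNS:
            if stem.startswith(table):
                grouped[table].append(p)
                break
    return grouped


def _age_to_years(age: str, cod: str) -> float | None:
    try:
        v = float(age)
    except (TypeError, ValueError):
        return None
    factor = _AGE_TO_YEARS.get(str(cod).strip().upper(), None)
    if factor is None:
        return None
    return v * factor


def _weight_to_kg(wt: str, cod: str) -> float | None:
    try:
        v = float(wt)
    except (TypeError, ValueError):
        return None
    cod = str(cod).strip().upper()
    if cod in ("KG", "KGS", ""):
        return v
    if cod in ("LBS", "LB"):
        return v * LB_TO_KG
    return None


def parse_tables(paths: Iterable[str | Path] | str | Path) -> IngestResult:
    """Read quarterly tables, deduplicate, and assemble :class:`ReportCase`s.

    ``paths`` is either a directory (all ``<TABLE>*.txt`` files inside are
    loaded) or an explicit collection of files.  Rows with the wrong field
    count are counted per table and logged, never silently dropped without
    trace; only strict 8-digit dates are parsed.
    """
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        paths = sorted(Path(paths).glob("*.txt"))
    elif isinstance(paths, (str, Path)):
        paths = [Path(paths)]
    grouped = _classify_files(paths)
    if not grouped["DEMO"]:
        raise FormatError("no DEMO table found among the input files")

    frames: dict[str, pd.DataFrame] = {}
    malformed: dict[str, int] = {}
    table_rows: dict[str, int] = {}
    for table, files in grouped.items():
        parts = []
        bad_total = 0
        for f in sorted(files):
            df, bad = _read_table(f, table)
            parts.append(df)
            bad_total += bad
        frames[table] = (
            pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=TABLE_COLUMNS[table])
        )
        malformed[table] = bad_total
        table_rows[table] = len(frames[table])

    demo = frames["DEMO"]
    demo = demo.assign(
        primaryid=pd.to_numeric(demo["primaryid"]),
        caseid=pd.to_numeric(demo["caseid"]),
    )
    kept = deduplicate(demo)
    removed = sorted(set(demo["primaryid"]) - set(kept["primaryid"]))
    kept_pids = set(kept["primaryid"].tolist())

    cases: dict[int, ReportCase] = {}
    for row in kept.itertuples(index=False):
        d = row._asdict()
        cases[int(d["primaryid"])] = ReportCase(
            caseid=int(d["caseid"]),
            primaryid=int(d["primaryid"]),
            fda_dt=parse_date8(d.get("fda_dt")),
            event_dt_raw=str(d.get("event_dt", "") or ""),
            sex=str(d.get("sex", "") or "").strip().upper(),
            age_years=_age_to_years(d.get("age", ""), d.get("age_cod", "")),
            weight_kg=_weight_to_kg(d.get("wt", ""), d.get("wt_cod", "")),
            occupation=str(d.get("occp_cod", "") or "").strip().upper(),
            country=str(d.get("reporter_country", "") or "").strip().upper(),
        )

    def _rows(table: str) -> Iterator[dict]:
        df = frames[table]
        if df.empty:
            return iter(())
        df = df.assign(primaryid=pd.to_numeric(df["primaryid"]))
        df = df[df["primaryid"].isin(kept_pids)]
        return (r._asdict() for r in df.itertuples(index=False))

    for d in _rows("DRUG"):
        role = str(d.get("role_cod", "") or "").strip().upper()
        seq = int(float(d.get("drug_seq", 0) or 0))
        cases[int(d["primaryid"])].drugs.append((seq, str(d.get("drugname", "") or ""), role))
    for d in _rows("REAC"):
        cases[int(d["primaryid"])].pts.append(str(d.get("pt", "") or "").strip())
    for d in _rows("OUTC"):
        cases[int(d["primaryid"])].outcomes.append(
            str(d.get("outc_cod", "") or "").strip().upper()
        )
    for d in _rows("THER"):
        seq = int(float(d.get("dsg_drug_seq", 0) or 0))
        cases[int(d["primaryid"])].therapy_starts.append(
            (seq, str(d.get("start_dt", "") or ""))
        )
    for d in _rows("INDI"):
        seq = int(float(d.get("indi_drug_seq", 0) or 0))
        cases[int(d["primaryid"])].indications.append(
            (seq, str(d.get("indi_pt", "") or "").strip())
        )

    return IngestResult(
        cases=list(cases.values()),
        removed_primaryids=[int(p) for p in removed],
        malformed_rows=malformed,
        table_rows=table_rows,
    )


def select_cohort(
    cases: Sequence[ReportCase],
    drug_synonyms: Sequence[str] = DEFAULT_SYNONYMS,
    indication_terms: Sequence[str] = DEFAULT_INDICATIONS,
    indication_any_drug: bool = False,
) -> list[ReportCase]:
    """Select cases with the target drug as primary suspect and a qualifying indication.

    A case qualifies when (i) some drug row's normalized name matches a
    synonym with role PS, and (ii) at least one indication PT matches the
    indication list (case-insensitive exact match).  By default indication
    rows must be linked (via drug sequence) to a matching target-drug row;
    ``indication_any_drug=True`` relaxes the link to any row in the report.
    Cases with no indication recorded are excluded.
    """
    if not drug_synonyms:
        raise ValueError("drug_synonyms must be non-empty")
    if not indication_terms:
        raise ValueError("indication_terms must be non-empty")
    syn = frozenset(normalize_name(s) for s in drug_synonyms)
    terms = frozenset(str(t).strip().casefold() for t in indication_terms)

    selected = []
    for case in cases:
        if not case.has_target_ps(syn):
            continue
        if not case.indications:
            continue
        if indication_any_drug:
            pool = [pt for _, pt in case.indications]
        else:
            target_seqs = set(case.drug_seqs_matching(syn))
            pool = [pt for seq, pt in case.indications if seq in target_seqs]
        if any(pt.strip().casefold() in terms for pt in pool):
            selected.append(case)
    return selected


def split_cohort(
    cases: Sequence[ReportCase],
    drug_synonyms: Sequence[str] = DEFAULT_SYNONYMS,
    indication_terms: Sequence[str] = DEFAULT_INDICATIONS,
    indication_any_drug: bool = False,
) -> tuple[list[ReportCase], list[ReportCase]]:
    """Split deduplicated cases into (cohort, background).

    The background comparator is every deduplicated report that does not
    qualify for the cohort — the standard full-database comparator.
    """
    cohort = select_cohort(cases, drug_synonyms, indication_terms, indication_any_drug)
    cohort_ids = {c.primaryid for c in cohort}
    background = [c for c in cases if c.primaryid not in cohort_ids]
    return cohort, background
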