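"""Descriptive cohort layer: demographics, therapy split, worst outcomes.

Age and weight are normalized (to years and kilograms) before binning; the
bins follow the conventional reporting layout: age <=17 / 18-64 / 65-85 /
>=86, weight <50 / 50-100 / >100 kg, with the 50 and 100 kg boundaries
assigned to the middle bin.  The per-case outcome is the most severe one
under the regulatory seriousness ranking DE > LT > HO > DS > CA > RI > OT.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from faerspv.ingest import OUTCOME_SEVERITY, ReportCase
from faerspv.vocab import DEFAULT_SYNONYMS, normalize_name

_SEVERITY_RANK = {code: i for i, code in enumerate(OUTCOME_SEVERITY)}


def worst_outcome(outcomes: Iterable[str]) -> str | None:
    """Most severe outcome code, or None for an empty set.

    Severity order: DE > LT > HO > DS > CA > RI > OT.
    """
    codes = [str(c).strip().upper() for c in outcomes if str(c).strip()]
    for code in codes:
        if code not in _SEVERITY_RANK:
            raise ValueError(f"unknown outcome code {code!r}")
    if not codes:
        return None
    return min(codes, key=lambda c: _SEVERITY_RANK[c])


def classify_therapy(
    case: ReportCase, drug_synonyms: Sequence[str] = DEFAULT_SYNONYMS
) -> str:
    """'combination' iff the case lists any distinct non-target drug (any role).

    Target-drug synonyms collapse to one drug, so a report naming both the
    generic and the trade name is still monotherapy.
    """
    syn = frozenset(normalize_name(s) for s in drug_synonyms)
    others = {
        normalize_name(name)
        for _, name, _ in case.drugs
        if normalize_name(name) not in syn and normalize_name(name)
    }
    return "combination" if others else "monotherapy"


def _age_bin(age: float | None) -> str:
    if age is None:
        return "missing"
    if age <= 17:
        return "<=17"
    if age <= 64:
        return "18-64"
    if age <= 85:
        return "65-85"
    return ">=86"


def _weight_bin(kg: float | None) -> str:
    if kg is None:
        return "missing"
    if kg < 50:
        return "<50 kg"
    if kg <= 100:
        return "50-100 kg"
    return ">100 kg"


def _sex_bin(sex: str) -> str:
    return sex if sex in ("F", "M") else "missing"


_AGE_ORDER = ["<=17", "18-64", "65-85", ">=86", "missing"]
_WT_ORDER = ["<50 kg", "50-100 kg", ">100 kg", "missing"]
_SEX_ORDER = ["F", "M", "missing"]


@dataclass
class CohortSummary:
    """Counts and percentages per characteristic; each partition sums to n."""

    n: int
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    yearly: pd.DataFrame | None = None


def _freq_table(values: Iterable[str], order: Sequence[str] | None, n: int) -> pd.DataFrame:
    counts = Counter(values)
    if order is None:
        order = sorted(counts, key=lambda k: (-counts[k], k))
    rows = [
        {"bin": b, "count": counts.get(b, 0), "percent": 100.0 * counts.get(b, 0) / n}
        for b in order
    ]
    extra = [k for k in counts if k not in set(order)]
    for b in sorted(extra):
        rows.append({"bin": b, "count": counts[b], "percent": 100.0 * counts[b] / n})
    return pd.DataFrame(rows)


def summarize(
    cases: Sequence[ReportCase], drug_synonyms: Sequence[str] = DEFAULT_SYNONYMS
) -> CohortSummary:
    """Tabulate demographics, therapy split, worst outcomes and yearly counts."""
    n = len(cases)
    if n == 0:
        raise ValueError("cannot summarize an empty cohort")
    summary = CohortSummary(n=n)
    summary.tables["age"] = _freq_table((_age_bin(c.age_years) for c in cases), _AGE_ORDER, n)
    summary.tables["sex"] = _freq_table((_sex_bin(c.sex) for c in cases), _SEX_ORDER, n)
    summary.tables["weight"] = _freq_table(
        (_weight_bin(c.weight_kg) for c in cases), _WT_ORDER, n
    )
    summary.tables["occupation"] = _freq_table(
        ((c.occupation or "missing") for c in cases), None, n
    )
    summary.tables["country"] = _freq_table(((c.country or "missing") for c in cases), None, n)
    summary.tables["therapy"] = _freq_table(
        (classify_therapy(c, drug_synonyms) for c in cases),
        ["monotherapy", "combination"],
        n,
    )
    summary.tables["worst_outcome"] = _freq_table(
        ((worst_outcome(c.outcomes) or "none") for c in cases),
        list(OUTCOME_SEVERITY) + ["none"],
        n,
    )
    years = Counter(c.receipt_year for c in cases if c.receipt_year is not None)
    summary.yearly = pd.DataFrame(
        [{"year": y, "count": years[y]} for y in sorted(years)]
    )
    return summary
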