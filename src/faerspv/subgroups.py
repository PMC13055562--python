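"""Stratified detection and between-stratum comparison with FDR control.

Two layers: (i) running the full joint-criteria detection inside a stratum
(female / male, monotherapy / combination) with both cohort and background
restricted to that stratum; (ii) a direct between-stratum reporting odds
ratio computed within the drug cohort only — a = stratum-A reports with the
PT, b = without, c / d likewise for stratum B — with a 1-df chi-square
p-value, Benjamini-Hochberg adjustment across the PTs entering the run, and
volcano coordinates (log2 ROR, -log10 adjusted p).  Orientation: stratum A
is female (or monotherapy), so ROR > 1 with adjusted p < 0.05 marks an event
more reported in females / without co-medication, ROR < 1 the converse.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from faerspv.ingest import ReportCase
from faerspv.signals import ContingencyTable, SignalResult, detect, prr_chi2, ror

logger = logging.getLogger(__name__)


@dataclass
class SubgroupComparison:
    pt: str
    a: int  # stratum A with PT
    b: int  # stratum A without
    c: int  # stratum B with PT
    d: int  # stratum B without
    ror: float = math.nan
    ror025: float = math.nan
    ror975: float = math.nan
    chi2: float = math.nan
    p: float = math.nan
    p_adj: float = math.nan
    log2_ror: float = math.nan
    neg_log10_padj: float = math.nan
    direction: str = "none"
    corrected: bool = False
    clamped: bool = False


def stratified_detect(
    cohort: Sequence[ReportCase],
    background: Sequence[ReportCase],
    stratum: Callable[[ReportCase], bool],
    level: str = "pt",
    pt_to_soc: Mapping[str, str] | None = None,
) -> tuple[list[SignalResult], set[str]]:
    """Joint-criteria detection with cohort AND background restricted to a stratum."""
    sub_cohort = [c for c in cohort if stratum(c)]
    sub_background = [c for c in background if stratum(c)]
    if not sub_cohort or not sub_background:
        logger.warning(
            "empty stratum (cohort=%d, background=%d); returning no results",
            len(sub_cohort),
            len(sub_background),
        )
        return [], set()
    return detect(sub_cohort, sub_background, level=level, pt_to_soc=pt_to_soc)


def between_group_ror(
    pt: str, cohort_a: Sequence[ReportCase], cohort_b: Sequence[ReportCase]
) -> SubgroupComparison:
    """Between-stratum ROR for one PT, computed within the drug cohort only.

    The chi-square statistic uses the same uncorrected form as the detection
    layer; its 1-df upper tail gives the p-value.  Adjusted-p fields are
    filled in later by :func:`fdr_adjust` / :func:`volcano_table`.
    """
    if not cohort_a or not cohort_b:
        raise ValueError("both strata must be non-empty")
    a = sum(1 for case in cohort_a if pt in set(case.pts))
    b = len(cohort_a) - a
    c = sum(1 for case in cohort_b if pt in set(case.pts))
    d = len(cohort_b) - c
    if a == 0 and c == 0:
        raise ValueError(f"PT {pt!r} occurs in neither stratum")
    t = ContingencyTable(a=a, b=b, c=c, d=d)
    est, lo, hi, _ = ror(t)
    _, chi2 = prr_chi2(t)
    _, corrected = t.corrected_cells()
    p = float(stats.chi2.sf(chi2, df=1))
    return SubgroupComparison(
        pt=pt, a=a, b=b, c=c, d=d, ror=est, ror025=lo, ror975=hi,
        chi2=chi2, p=p, corrected=corrected,
    )


def fdr_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, output in input order."""
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def shared_positive_pts(
    results_a: Sequence[SignalResult], results_b: Sequence[SignalResult]
) -> list[str]:
    """PTs signal-positive in BOTH strata — the explicit shared-signal filter."""
    pos_a = {r.label for r in results_a if r.signal_positive}
    pos_b = {r.label for r in results_b if r.signal_positive}
    return sorted(pos_a & pos_b)


def compare_strata(
    pts: Sequence[str],
    cohort_a: Sequence[ReportCase],
    cohort_b: Sequence[ReportCase],
) -> list[SubgroupComparison]:
    """Between-stratum comparison for a PT family, with FDR across that family."""
    comparisons = [between_group_ror(pt, cohort_a, cohort_b) for pt in pts]
    adj = fdr_adjust([c.p for c in comparisons])
    for comp, pa in zip(comparisons, adj):
        comp.p_adj = pa
    return comparisons


def volcano_table(comparisons: Sequence[SubgroupComparison]) -> pd.DataFrame:
    """Volcano coordinates: log2(ROR) vs -log10(adjusted p), plus direction.

    Direction 'A' (female / monotherapy) iff ROR > 1 and adjusted p < 0.05;
    'B' iff ROR < 1 and adjusted p < 0.05; otherwise 'none'.  An adjusted p
    of exactly 0 is clamped to the smallest positive float and flagged.
    """
    tiny = sys.float_info.min
    rows = []
    for comp in comparisons:
        p_adj = comp.p_adj
        clamped = False
        if p_adj == 0.0:
            p_adj = tiny
            clamped = True
        comp.log2_ror = math.log2(comp.ror) if comp.ror > 0 else -math.inf
        comp.neg_log10_padj = -math.log10(p_adj)
        comp.clamped = clamped
        if comp.p_adj < 0.05 and comp.ror > 1.0:
            comp.direction = "A"
        elif comp.p_adj < 0.05 and comp.ror < 1.0:
            comp.direction = "B"
        else:
            comp.direction = "none"
        rows.append(
            {
                "pt": comp.pt,
                "a": comp.a,
                "b": comp.b,
                "c": comp.c,
                "d": comp.d,
                "ror": comp.ror,
                "ror025": comp.ror025,
                "ror975": comp.ror975,
                "chi2": comp.chi2,
                "p": comp.p,
                "p_adj": comp.p_adj,
                "log2_ror": comp.log2_ror,
                "neg_log10_padj": comp.neg_log10_padj,
                "direction": comp.direction,
                "corrected": comp.corrected,
                "clamped": comp.clamped,
            }
        )
    return pd.DataFrame(rows)


def sex_stratum(sex: str) -> Callable[[ReportCase], bool]:
    """Predicate for a sex stratum; cases with missing sex never match."""
    sex = sex.upper()
    return lambda case: case.sex == sex


def therapy_stratum(
    kind: str, drug_synonyms: Sequence[str] | None = None
) -> Callable[[ReportCase], bool]:
    """Predicate for the monotherapy / combination stratum.

    A report is monotherapy when it lists a single distinct drug after
    collapsing target-drug synonyms; for cohort reports this coincides with
    the absence of concomitant medication, and the same rule extends to
    background reports (whose suspect drug is not the target).
    """
    from faerspv.vocab import DEFAULT_SYNONYMS, normalize_name

    if kind not in ("monotherapy", "combination"):
        raise ValueError(f"kind must be 'monotherapy' or 'combination', got {kind!r}")
    syn = frozenset(normalize_name(s) for s in (drug_synonyms or DEFAULT_SYNONYMS))

    def predicate(case: ReportCase) -> bool:
        names = set()
        for _, name, _ in case.drugs:
            norm = normalize_name(name)
            if norm:
                names.add("__target__" if norm in syn else norm)
        mono = len(names) <= 1
        return mono if kind == "monotherapy" else not mono

    return predicate
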