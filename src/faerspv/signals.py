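"""Disproportionality statistics on 2x2 report tables.

For one (drug, event) pair the table counts reports:

    a = target drug & target event      b = target drug & other events
    c = other drugs & target event      d = other drugs & other events

and the detection statistics are computed exactly as conventionally printed:

    ROR  = ad / bc,  SE(lnROR) = sqrt(1/a + 1/b + 1/c + 1/d),
    95% CI = exp(ln ROR +/- 1.96 SE)
    PRR  = [a(c+d)] / [c(a+b)]
    chi2 = (ad - bc)^2 (a+b+c+d) / [(a+b)(c+d)(a+c)(b+d)]   (no continuity corr.)
    IC   = log2[ a N / ((a+c)(a+b)) ]                        (raw form)

with the joint positivity rule ROR025 > 1, PRR > 2, chi2 > 4, a >= 3 and
IC025 > 0 (all strict).  The IC credible interval uses the closed-form
posterior-moment approximation of the original BCPNN formulation (Bate et
al. 1998): Dirichlet/Beta priors adding 1 to each margin cell (alpha1 =
beta1 = gamma11 = 1, alpha = beta = 2) and a joint-cell prior weight gamma
calibrated so the prior expectation of IC is zero.

Zero-cell policy: when any of b, c, d is zero (with a >= 1), 0.5 is added to
all four cells for the ROR/PRR/chi2 computation and the result is flagged
``corrected``; the a >= 3 signal gate always uses the raw ``a``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from faerspv.ingest import FormatError, ReportCase

Z95 = 1.96
LN2 = math.log(2.0)


class UndefinedResultError(ValueError):
    """The statistic is undefined for this table even after correction."""


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("b", self.b), ("c", self.c), ("d", self.d)):
            if v < 0:
                raise ValueError(f"cell {name} must be >= 0, got {v}")
        if self.n == 0:
            raise UndefinedResultError("all four cells are zero")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def corrected_cells(self) -> tuple[tuple[float, float, float, float], bool]:
        """Raw cells, or all four +0.5 when any of b, c, d is zero."""
        if min(self.b, self.c, self.d) == 0:
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5), True
        return (float(self.a), float(self.b), float(self.c), float(self.d)), False


@dataclass
class SignalResult:
    label: str
    level: str  # "pt" or "soc"
    table: ContingencyTable
    ror: float = math.nan
    ror025: float = math.nan
    ror975: float = math.nan
    se_ln_ror: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ic_raw: float = math.nan
    corrected: bool = False
    ror_positive: bool = False
    prr_positive: bool = False
    ic_positive: bool = False
    signal_positive: bool = False


def ror(t: ContingencyTable) -> tuple[float, float, float, float]:
    """Reporting odds ratio with its 95% CI: (estimate, ror025, ror975, se_ln_ror)."""
    (a, b, c, d), _ = t.corrected_cells()
    if a == 0 or c == 0:
        # a=0 only reachable uncorrected (b,c,d all > 0): the odds ratio is 0
        # with an unbounded lower interval; callers gate on a >= 3 anyway.
        return 0.0, 0.0, math.inf, math.inf
    est = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    lo = math.exp(math.log(est) - Z95 * se)
    hi = math.exp(math.log(est) + Z95 * se)
    return est, lo, hi, se


def prr_chi2(t: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and the (uncorrected) chi-square statistic."""
    (a, b, c, d), _ = t.corrected_cells()
    n = a + b + c + d
    if c == 0 or (a + b) == 0:
        raise UndefinedResultError("PRR denominator is zero even after correction")
    prr = (a * (c + d)) / (c * (a + b))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise UndefinedResultError("chi-square denominator is zero even after correction")
    chi2 = (a * d - b * c) ** 2 * n / denom
    return prr, chi2


def ic_raw(t: ContingencyTable) -> float:
    """Raw information component log2(aN / ((a+c)(a+b))); -inf when a = 0."""
    if t.a == 0:
        return -math.inf
    return math.log2(t.a * t.n / ((t.a + t.c) * (t.a + t.b)))


def bcpnn_ic(t: ContingencyTable) -> tuple[float, float]:
    """Shrunk information component and its lower bound: (ic, ic025).

    Posterior-moment approximation with margin priors alpha1 = beta1 = 1
    (totals alpha = beta = 2), joint prior gamma11 = 1 and gamma scaled so
    the prior IC expectation is zero; ic025 = E(IC) - 2 sqrt(V(IC)).
    """
    a, n = t.a, t.n
    cx = t.a + t.b  # drug margin
    cy = t.a + t.c  # event margin
    alpha1 = beta1 = gamma11 = 1.0
    alpha = beta = 2.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((cx + alpha1) * (cy + beta1))
    e_ic = math.log2(
        (a + gamma11) * (n + alpha) * (n + beta)
        / ((n + gamma) * (cx + alpha1) * (cy + beta1))
    )
    v_ic = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - cx + alpha - alpha1) / ((cx + alpha1) * (1 + n + alpha))
        + (n - cy + beta - beta1) / ((cy + beta1) * (1 + n + beta))
    ) / (LN2 ** 2)
    return e_ic, e_ic - 2.0 * math.sqrt(v_ic)


def evaluate_signal(r: SignalResult) -> SignalResult:
    """Set the positivity flags from the joint criteria (all strict)."""
    a = r.table.a
    r.ror_positive = (r.ror025 > 1.0) and (a >= 3)
    r.prr_positive = (r.prr > 2.0) and (r.chi2 > 4.0) and (a >= 3)
    r.ic_positive = r.ic025 > 0.0
    r.signal_positive = r.ror_positive and r.prr_positive and r.ic_positive
    return r


def compute_signal(label: str, level: str, t: ContingencyTable) -> SignalResult:
    """All statistics plus flags for one event label."""
    res = SignalResult(label=label, level=level, table=t)
    res.ror, res.ror025, res.ror975, res.se_ln_ror = ror(t)
    res.prr, res.chi2 = prr_chi2(t)
    res.ic, res.ic025 = bcpnn_ic(t)
    res.ic_raw = ic_raw(t)
    _, res.corrected = t.corrected_cells()
    return evaluate_signal(res)


def _labels_per_case(case: ReportCase, level: str, pt_to_soc: Mapping[str, str] | None,
                     unmapped: set[str]) -> set[str]:
    # Report-level counting: a case contributes at most once per label.
    if level == "pt":
        return {pt for pt in case.pts if pt}
    assert pt_to_soc is not None
    labels = set()
    for pt in case.pts:
        soc = pt_to_soc.get(pt.strip().casefold())
        if soc is None:
            if pt:
                unmapped.add(pt)
            continue
        labels.add(soc)
    return labels


def detect(
    cohort: Sequence[ReportCase],
    background: Sequence[ReportCase],
    level: str = "pt",
    pt_to_soc: Mapping[str, str] | None = None,
) -> tuple[list[SignalResult], set[str]]:
    """One :class:`SignalResult` per event label occurring in the cohort.

    Counting is report-level: a report with the same PT listed twice adds 1,
    not 2, to cell ``a``.  At SOC level ``pt_to_soc`` (case-insensitive PT
    keys) maps terms; PTs without a mapping are returned in the second
    element rather than silently dropped.  Results sorted by descending ROR.
    """
    if level not in ("pt", "soc"):
        raise ValueError(f"level must be 'pt' or 'soc', got {level!r}")
    if level == "soc" and pt_to_soc is None:
        raise ValueError("SOC-level detection requires a pt_to_soc mapping")
    if not background:
        raise ValueError("background must be non-empty")
    mapping = (
        {str(k).strip().casefold(): v for k, v in pt_to_soc.items()} if pt_to_soc else None
    )

    unmapped: set[str] = set()
    cohort_counts: Counter[str] = Counter()
    for case in cohort:
        cohort_counts.update(_labels_per_case(case, level, mapping, unmapped))
    bg_counts: Counter[str] = Counter()
    for case in background:
        bg_counts.update(_labels_per_case(case, level, mapping, set()))

    n_cohort = len(cohort)
    n_bg = len(background)
    results = []
    for label, a in cohort_counts.items():
        c = bg_counts.get(label, 0)
        t = ContingencyTable(a=a, b=n_cohort - a, c=c, d=n_bg - c)
        results.append(compute_signal(label, level, t))
    results.sort(key=lambda r: (-(r.ror if math.isfinite(r.ror) else math.inf), r.label))
    return results, unmapped


def results_table(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Tidy frame of all statistics and flags, one row per event label."""
    rows = []
    for r in results:
        rows.append(
            {
                "label": r.label,
                "level": r.level,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "ror": r.ror,
                "ror025": r.ror025,
                "ror975": r.ror975,
                "se_ln_ror": r.se_ln_ror,
                "prr": r.prr,
                "chi2": r.chi2,
                "ic": r.ic,
                "ic025": r.ic025,
                "ic_raw": r.ic_raw,
                "corrected": r.corrected,
                "ror_positive": r.ror_positive,
                "prr_positive": r.prr_positive,
                "ic_positive": r.ic_positive,
                "signal_positive": r.signal_positive,
            }
        )
    return pd.DataFrame(rows)


def load_pt_soc_map(path) -> dict[str, str]:
    """Read a two-column (pt, soc) TSV into a case-insensitive mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"pt", "soc"}.issubset(df.columns):
        raise FormatError("PT->SOC map needs columns 'pt' and 'soc'")
    return {str(r.pt).strip().casefold(): str(r.soc).strip() for r in df.itertuples()}
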