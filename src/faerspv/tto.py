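"""Time-to-onset (TTO) analysis: cleaning, Weibull shape test, log-rank by sex.

TTO is the whole-day interval between the event date and the start of
target-drug therapy.  Records are excluded (and counted, by reason) when
either date is missing or not full 8-digit precision, or when the interval
is <= 0 (event on or before the start date).  The Weibull shape-parameter
(WSP) test fits scale alpha and shape beta by maximum likelihood: beta < 1
(hazard decreasing) is the "early failure" pattern, beta ~ 1 random,
beta > 1 "wear-out"; classification uses the 95% CI of beta, built as a
Wald interval on the log-parameters from the observed information.

Spontaneous reports are all events by construction (a report exists because
the event happened), so there is no censoring model: the sex comparison is
a standard two-group log-rank test on fully observed onset times, with the
per-sex cumulative incidence given by the empirical CDF over onset days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy.optimize import brentq
from scipy.special import logsumexp

from faerspv.ingest import ReportCase, parse_date8
from faerspv.vocab import DEFAULT_SYNONYMS, normalize_name

MIN_FIT_N = 30


class InsufficientDataError(ValueError):
    """Too few onset times to fit the Weibull model."""


class FitError(RuntimeError):
    """Maximum-likelihood estimation failed to converge."""


@dataclass(frozen=True)
class TTORecord:
    caseid: int
    onset_days: int
    sex: str

    def __post_init__(self) -> None:
        if self.onset_days < 1:
            raise ValueError(f"onset_days must be >= 1, got {self.onset_days}")


@dataclass
class WeibullFit:
    alpha: float  # scale, days
    alpha_ci: tuple[float, float]
    beta: float  # shape, dimensionless
    beta_ci: tuple[float, float]
    n: int
    median: float  # empirical, not fitted
    iqr: float
    min: float
    max: float
    failure_type: str = "random"


def compute_tto(
    cases: Sequence[ReportCase],
    drug_synonyms: Sequence[str] = DEFAULT_SYNONYMS,
) -> tuple[list[TTORecord], dict[str, int]]:
    """Onset intervals for target-drug therapy, with exclusion counts by reason.

    The earliest valid start date among the target drug's therapy rows is
    used (first exposure).  Returns ``(records, exclusions)`` where the
    exclusion reasons are ``missing_start``, ``missing_event``
    (incomplete or absent dates) and ``event_before_start`` (interval <= 0,
    including same-day events, consistent with a printed minimum of 1 day).
    """
    syn = frozenset(normalize_name(s) for s in drug_synonyms)
    records: list[TTORecord] = []
    exclusions = {"missing_start": 0, "missing_event": 0, "event_before_start": 0}
    for case in cases:
        target_seqs = set(case.drug_seqs_matching(syn))
        starts = [
            parse_date8(raw)
            for seq, raw in case.therapy_starts
            if seq in target_seqs and parse_date8(raw) is not None
        ]
        if not starts:
            exclusions["missing_start"] += 1
            continue
        event = parse_date8(case.event_dt_raw)
        if event is None:
            exclusions["missing_event"] += 1
            continue
        onset = (event - min(starts)).days
        if onset <= 0:
            exclusions["event_before_start"] += 1
            continue
        records.append(TTORecord(caseid=case.caseid, onset_days=onset, sex=case.sex))
    return records, exclusions


def _shape_score(beta: float, log_t: np.ndarray) -> float:
    # d/d(beta) of the profile log-likelihood: weighted-mean identity with
    # logsumexp weights, stable for large beta * log(t).
    w = beta * log_t
    m = w.max()
    e = np.exp(w - m)
    weighted_mean = float((e * log_t).sum() / e.sum())
    return weighted_mean - 1.0 / beta - float(log_t.mean())


def _neg_loglik(log_beta: float, log_alpha: float, t: np.ndarray, log_t: np.ndarray) -> float:
    beta = math.exp(log_beta)
    alpha = math.exp(log_alpha)
    n = t.size
    ll = (
        n * math.log(beta)
        - n * beta * math.log(alpha)
        + (beta - 1.0) * float(log_t.sum())
        - float(np.exp(beta * (log_t - math.log(alpha))).sum())
    )
    return -ll


def weibull_fit(onsets: Sequence[float]) -> WeibullFit:
    """Maximum-likelihood Weibull fit with Wald CIs on the log-parameters.

    The shape solves the standard profile score equation (found by Brent's
    method on an expanding bracket); the scale then has the closed form
    alpha = (mean t^beta)^(1/beta).  Standard errors come from the observed
    information of the log-parameterized likelihood (central-difference
    Hessian), so the CIs are positivity-respecting.  The median, IQR, min
    and max are empirical summaries of the input, not fitted quantities.
    """
    t = np.asarray(list(onsets), dtype=float)
    if t.size < MIN_FIT_N:
        raise InsufficientDataError(
            f"need at least {MIN_FIT_N} onset times, got {t.size}"
        )
    if np.any(t <= 0):
        raise ValueError("all onset times must be positive")
    log_t = np.log(t)
    if np.allclose(log_t, log_t[0]):
        raise FitError("degenerate sample: all onset times identical")

    lo, hi = 1e-3, 8.0
    while _shape_score(hi, log_t) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise FitError("shape estimate diverged; no finite root of the score")
    try:
        beta = float(brentq(_shape_score, lo, hi, args=(log_t,), xtol=1e-12))
    except ValueError as exc:  # no sign change on the bracket
        raise FitError(f"shape root-finding failed: {exc}") from exc
    log_alpha = float((logsumexp(beta * log_t) - math.log(t.size)) / beta)
    alpha = math.exp(log_alpha)

    # Observed information in (log beta, log alpha) by central differences.
    h = 1e-5
    lb, la = math.log(beta), log_alpha

    def f(x: float, y: float) -> float:
        return _neg_loglik(x, y, t, log_t)

    f0 = f(lb, la)
    d2_bb = (f(lb + h, la) - 2 * f0 + f(lb - h, la)) / h**2
    d2_aa = (f(lb, la + h) - 2 * f0 + f(lb, la - h)) / h**2
    d2_ba = (
        f(lb + h, la + h) - f(lb + h, la - h) - f(lb - h, la + h) + f(lb - h, la - h)
    ) / (4 * h**2)
    info = np.array([[d2_bb, d2_ba], [d2_ba, d2_aa]])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError("observed information is singular") from exc
    if cov[0, 0] <= 0 or cov[1, 1] <= 0:
        raise FitError("observed information is not positive definite")
    se_lb, se_la = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])

    beta_ci = (beta * math.exp(-1.96 * se_lb), beta * math.exp(1.96 * se_lb))
    alpha_ci = (alpha * math.exp(-1.96 * se_la), alpha * math.exp(1.96 * se_la))

    q25, q50, q75 = np.percentile(t, [25, 50, 75])
    fit = WeibullFit(
        alpha=alpha,
        alpha_ci=alpha_ci,
        beta=beta,
        beta_ci=beta_ci,
        n=int(t.size),
        median=float(q50),
        iqr=float(q75 - q25),
        min=float(t.min()),
        max=float(t.max()),
    )
    fit.failure_type = classify_failure(fit)
    return fit


def classify_failure(fit: WeibullFit) -> str:
    """'early' iff the beta CI lies below 1, 'wear-out' iff above, else 'random'."""
    lo, hi = fit.beta_ci
    if hi < 1.0:
        return "early"
    if lo > 1.0:
        return "wear-out"
    return "random"


def logrank_by_sex(
    records: Sequence[TTORecord],
) -> tuple[float, float, pd.DataFrame]:
    """Two-group log-rank test on onset times plus per-sex cumulative incidence.

    All records are observed events (no censoring).  Returns ``(statistic,
    p, table)`` where the table holds the empirical CDF per sex over onset
    days (columns: day, sex, cum_incidence).
    """
    by_sex: dict[str, list[int]] = {}
    for r in records:
        if r.sex in ("F", "M"):
            by_sex.setdefault(r.sex, []).append(r.onset_days)
    if len(by_sex) < 2 or any(len(v) == 0 for v in by_sex.values()):
        raise ValueError("need records from both sexes for the log-rank comparison")

    t_f = np.asarray(by_sex["F"], dtype=float)
    t_m = np.asarray(by_sex["M"], dtype=float)
    res = logrank_test(
        t_f, t_m, event_observed_A=np.ones_like(t_f), event_observed_B=np.ones_like(t_m)
    )
    rows = []
    for sex, times in (("F", t_f), ("M", t_m)):
        days = np.sort(np.unique(times))
        cdf = np.searchsorted(np.sort(times), days, side="right") / times.size
        rows.append(pd.DataFrame({"day": days, "sex": sex, "cum_incidence": cdf}))
    table = pd.concat(rows, ignore_index=True)
    return float(res.test_statistic), float(res.p_value), table


def tto_table(records: Sequence[TTORecord]) -> pd.DataFrame:
    """Per-record TTO frame (caseid, onset_days, sex)."""
    return pd.DataFrame(
        [{"caseid": r.caseid, "onset_days": r.onset_days, "sex": r.sex} for r in records]
    )


def fit_summary_table(fit: WeibullFit) -> pd.DataFrame:
    """One-row frame mirroring the usual TTO table layout."""
    return pd.DataFrame(
        [
            {
                "n": fit.n,
                "median": fit.median,
                "iqr": fit.iqr,
                "min": fit.min,
                "max": fit.max,
                "alpha": fit.alpha,
                "alpha_lo": fit.alpha_ci[0],
                "alpha_hi": fit.alpha_ci[1],
                "beta": fit.beta,
                "beta_lo": fit.beta_ci[0],
                "beta_hi": fit.beta_ci[1],
                "failure_type": fit.failure_type,
            }
        ]
    )
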