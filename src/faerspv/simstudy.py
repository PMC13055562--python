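"""Simulation studies of the pipeline's operating characteristics.

These are the package's calibration experiments: parameter-recovery runs
for the Weibull time-to-onset model and the ROR estimator (executed through
the full generate -> ingest -> detect path), a median-recovery check for the
TTO cleaning stage, and null-calibration runs measuring false-positive
rates when the generator injects no effect.  Problem sizes default to the
study-scale values used throughout the package (onset n = 15,682; roughly
1,000 target-PT reports per detection run).
"""

from __future__ import annotations

import math
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from faerspv.ingest import parse_tables, split_cohort
from faerspv.signals import detect
from faerspv.subgroups import compare_strata, sex_stratum, stratified_detect
from faerspv.synthetic import (
    GeneratorConfig,
    _DEFAULT_BACKGROUND_PTS,
    _event_prob_given_target,
    generate_extract,
)
from faerspv.tto import compute_tto, weibull_fit

TTO_N = 15_682
TTO_SCALE = 912.75
TTO_SHAPE = 0.73
_SEED_MOD = 2**31


def _sub_seed(seed: int, i: int) -> int:
    return (seed * 1009 + i) % _SEED_MOD


def weibull_recovery(
    n_seeds: int = 50, seed: int = 1, n: int = TTO_N,
    scale: float = TTO_SCALE, shape: float = TTO_SHAPE,
):
    """ML fits on repeated Weibull samples at the study's size and parameters."""
    fits = []
    for i in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, i))
        t = rng.weibull(shape, n) * scale
        fits.append(weibull_fit(t))
    return fits


def _recovery_config(pt: str, true_ror: float, p_event_background: float,
                     sex: str, n_target_pt: int, seed: int) -> GeneratorConfig:
    p_target = 0.35
    q = _event_prob_given_target(true_ror, p_event_background)
    n_reports = math.ceil(n_target_pt / (p_target * q))
    background = tuple(
        (name, p_event_background if name == pt else p) for name, p in _DEFAULT_BACKGROUND_PTS
    )
    return GeneratorConfig(
        n_reports=n_reports,
        p_target_drug=p_target,
        background_pts=background,
        target_effects=((pt, true_ror),),
        sex_multipliers=(),
        p_female=1.0 if sex == "F" else 0.0,
        p_duplicate=0.02,
        p_missing_demo=0.0,
        p_missing_date=0.0,
        seed=seed,
    )


@dataclass
class RorRecoveryRun:
    estimate: float
    lo: float
    hi: float
    a: int
    covered: bool  # does the estimate's own 95% CI contain the truth?


def ror_recovery_run(
    pt: str, true_ror: float, sex: str, seed: int,
    n_target_pt: int = 1000, p_event_background: float = 0.02,
) -> RorRecoveryRun:
    """One full generate -> ingest -> stratified-detect cycle for one PT.

    The extract is single-sex so the configured truth is exactly the
    subgroup ROR; detection runs inside that sex stratum.
    """
    cfg = _recovery_config(pt, true_ror, p_event_background, sex, n_target_pt, seed)
    with tempfile.TemporaryDirectory() as d:
        generate_extract(cfg, d)
        cohort, background = split_cohort(parse_tables(d).cases)
    results, _ = stratified_detect(cohort, background, sex_stratum(sex))
    (res,) = [r for r in results if r.label == pt]
    covered = res.ror025 <= true_ror <= res.ror975
    return RorRecoveryRun(
        estimate=res.ror, lo=res.ror025, hi=res.ror975, a=res.table.a, covered=covered
    )


def ror_recovery(
    pt: str, true_ror: float, sex: str, n_seeds: int = 50, seed: int = 1,
    n_target_pt: int = 1000, p_event_background: float = 0.02,
) -> list[RorRecoveryRun]:
    return [
        ror_recovery_run(
            pt, true_ror, sex, _sub_seed(seed, i), n_target_pt, p_event_background
        )
        for i in range(n_seeds)
    ]


def median_recovery(
    target_median: float = 620.0, n_seeds: int = 5, seed: int = 1,
    n: int = TTO_N, shape: float = TTO_SHAPE,
) -> list[float]:
    """Empirical medians from the TTO stage with the onset scale calibrated
    so the theoretical Weibull median equals ``target_median``."""
    scale = target_median / math.log(2.0) ** (1.0 / shape)
    medians = []
    for i in range(n_seeds):
        sub = _sub_seed(seed, i)
        # generate enough reports that the cleaned TTO set reaches n
        cfg = GeneratorConfig(
            n_reports=math.ceil(n / 0.9 * 1.02),
            p_target_drug=0.9,
            p_missing_date=0.0,
            p_duplicate=0.0,
            onset_scale_days=scale,
            onset_shape=shape,
            seed=sub,
        )
        with tempfile.TemporaryDirectory() as d:
            generate_extract(cfg, d)
            cohort, _ = split_cohort(parse_tables(d).cases)
        records, _ = compute_tto(cohort)
        onsets = np.array([r.onset_days for r in records], dtype=float)[:n]
        medians.append(float(np.median(onsets)))
    return medians


@dataclass
class NullCalibrationResult:
    n_pt_tests: int
    n_false_positives: int
    n_sex_comparisons: int
    n_sex_significant: int

    @property
    def fp_rate(self) -> float:
        return self.n_false_positives / self.n_pt_tests

    @property
    def sex_significant_fraction(self) -> float:
        if self.n_sex_comparisons == 0:
            return 0.0
        return self.n_sex_significant / self.n_sex_comparisons


def null_calibration(
    n_seeds: int = 50, seed: int = 1, n_reports: int = 12_000
) -> NullCalibrationResult:
    """False-positive behaviour with no injected effects.

    Every PT's true ROR is 1 and the sexes are exchangeable, so any joint
    signal is a false positive and any FDR-significant between-sex PT a
    false discovery.
    """
    null_pts = {name for name, _ in _DEFAULT_BACKGROUND_PTS}
    n_tests = fp = n_comp = n_sig = 0
    for i in range(n_seeds):
        cfg = GeneratorConfig(
            n_reports=n_reports,
            target_effects=(),
            sex_multipliers=(),
            p_duplicate=0.02,
            p_missing_demo=0.0,
            p_missing_date=0.0,
            seed=_sub_seed(seed, i),
        )
        with tempfile.TemporaryDirectory() as d:
            generate_extract(cfg, d)
            cohort, background = split_cohort(parse_tables(d).cases)
        results, _ = detect(cohort, background)
        for r in results:
            if r.label in null_pts:
                n_tests += 1
                fp += r.signal_positive
        females = [c for c in cohort if c.sex == "F"]
        males = [c for c in cohort if c.sex == "M"]
        pts_f = {pt for c in females for pt in c.pts}
        pts_m = {pt for c in males for pt in c.pts}
        family = sorted((pts_f & pts_m) & null_pts)
        if family:
            comparisons = compare_strata(family, females, males)
            n_comp += len(comparisons)
            n_sig += sum(c.p_adj < 0.05 for c in comparisons)
    return NullCalibrationResult(n_tests, fp, n_comp, n_sig)
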