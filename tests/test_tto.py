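"""Time-to-onset cleaning, Weibull ML fit, failure typing, log-rank."""

import numpy as np
import pytest
from lifelines import WeibullFitter
from lifelines.statistics import logrank_test

from faerspv.tto import (
    InsufficientDataError,
    TTORecord,
    WeibullFit,
    classify_failure,
    compute_tto,
    logrank_by_sex,
    weibull_fit,
)
from tests.conftest import make_case


def _dated_case(caseid, start, event, sex="F"):
    return make_case(
        caseid=caseid,
        sex=sex,
        therapy_starts=[(1, start)],
        event_dt_raw=event,
    )


class TestComputeTto:
    def test_whole_day_difference(self):
        records, _ = compute_tto([_dated_case(1, "20200101", "20200111")])
        assert records[0].onset_days == 10

    def test_event_before_start_excluded_with_reason(self):
        _, excl = compute_tto([_dated_case(1, "20200101", "20191231")])
        assert excl["event_before_start"] == 1

    def test_same_day_event_excluded(self):
        records, excl = compute_tto([_dated_case(1, "20200101", "20200101")])
        assert records == [] and excl["event_before_start"] == 1

    def test_partial_date_excluded_as_incomplete(self):
        _, excl = compute_tto([_dated_case(1, "20200101", "202001")])
        assert excl["missing_event"] == 1

    def test_missing_start_excluded(self):
        case = make_case(caseid=1, therapy_starts=[], event_dt_raw="20200111")
        _, excl = compute_tto([case])
        assert excl["missing_start"] == 1

    def test_earliest_target_start_used(self):
        case = make_case(
            caseid=1,
            drugs=[(1, "INFLIXIMAB", "PS"), (2, "INFLIXIMAB", "SS"), (3, "PREDNISONE", "C")],
            therapy_starts=[(2, "20200101"), (1, "20200301"), (3, "20190101")],
            event_dt_raw="20200311",
        )
        records, _ = compute_tto([case])
        # prednisone's earlier start must not count; infliximab first exposure does
        assert records[0].onset_days == (np.datetime64("2020-03-11") - np.datetime64("2020-01-01")).astype(int)


class TestWeibullFit:
    def test_exponential_sample_recovers_unit_shape(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(500.0, 10_000)
        fit = weibull_fit(t)
        assert 0.97 <= fit.beta <= 1.03
        assert fit.failure_type == "random"

    def test_matches_independent_ml_fitter(self):
        rng = np.random.default_rng(4)
        t = rng.weibull(0.73, 4000) * 912.75
        fit = weibull_fit(t)
        oracle = WeibullFitter().fit(t, np.ones_like(t))
        assert fit.alpha == pytest.approx(float(oracle.lambda_), rel=1e-5)
        assert fit.beta == pytest.approx(float(oracle.rho_), rel=1e-5)

    def test_summary_statistics_are_empirical(self):
        rng = np.random.default_rng(5)
        t = np.round(rng.weibull(0.9, 500) * 300 + 1)
        fit = weibull_fit(t)
        assert fit.median == np.percentile(t, 50)
        assert fit.min == t.min() and fit.max == t.max()

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            weibull_fit([1.0] * 10)

    def test_nonpositive_onset_rejected(self):
        with pytest.raises(ValueError):
            weibull_fit([0.0] + [1.0] * 50)

    @pytest.mark.parametrize("beta", [0.5, 0.73, 1.0, 1.5])
    def test_shape_bias_small_at_scale(self, beta):
        # 200-replicate Monte Carlo at n = 15,000: |bias| < 2% of beta
        rng = np.random.default_rng(int(beta * 100))
        draws = rng.weibull(beta, size=(200, 15_000)) * 900.0
        estimates = [weibull_fit(row).beta for row in draws]
        assert abs(np.mean(estimates) - beta) < 0.02 * beta


class TestClassifyFailure:
    @pytest.mark.parametrize(
        "beta,ci,expected",
        [
            (0.73, (0.72, 0.74), "early"),
            (1.0, (0.9, 1.1), "random"),
            (1.5, (1.3, 1.7), "wear-out"),
        ],
    )
    def test_rules(self, beta, ci, expected):
        fit = WeibullFit(
            alpha=900, alpha_ci=(850, 950), beta=beta, beta_ci=ci,
            n=100, median=600, iqr=900, min=1, max=5000,
        )
        assert classify_failure(fit) == expected


class TestLogrank:
    def _records(self, times_f, times_m):
        recs = [TTORecord(i, int(t), "F") for i, t in enumerate(times_f, 1)]
        recs += [TTORecord(10_000 + i, int(t), "M") for i, t in enumerate(times_m, 1)]
        return recs

    def test_label_swap_symmetric(self):
        rng = np.random.default_rng(6)
        f = np.ceil(rng.weibull(0.8, 300) * 400)
        m = np.ceil(rng.weibull(0.8, 300) * 500)
        s1, p1, _ = logrank_by_sex(self._records(f, m))
        s2, p2, _ = logrank_by_sex(self._records(m, f))
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_scale_shift_detected(self):
        rng = np.random.default_rng(7)
        f = np.ceil(rng.weibull(1.0, 1000) * 300)
        m = np.ceil(rng.weibull(1.0, 1000) * 600)
        _, p, _ = logrank_by_sex(self._records(f, m))
        assert p < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_by_sex([TTORecord(1, 5, "F"), TTORecord(2, 7, "F")])

    def test_cumulative_incidence_is_cdf(self):
        rng = np.random.default_rng(8)
        recs = self._records(
            np.ceil(rng.weibull(1.0, 50) * 100), np.ceil(rng.weibull(1.0, 50) * 100)
        )
        _, _, table = logrank_by_sex(recs)
        for sex, grp in table.groupby("sex"):
            vals = grp.sort_values("day")["cum_incidence"].to_numpy()
            assert np.all(np.diff(vals) >= 0)
            assert vals[-1] == pytest.approx(1.0)

    def test_null_rejection_rate_is_nominal(self):
        # identical distributions: alpha = 0.05 test rejects 3-7% of the time
        rng = np.random.default_rng(9)
        rejections = 0
        n_seeds = 500
        for _ in range(n_seeds):
            f = np.ceil(rng.weibull(0.9, 150) * 400)
            m = np.ceil(rng.weibull(0.9, 150) * 400)
            _, p, _ = logrank_by_sex(self._records(f, m))
            rejections += p < 0.05
        assert 0.03 <= rejections / n_seeds <= 0.07

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(10)
        f = np.ceil(rng.weibull(0.9, 60) * 300)
        m = np.ceil(rng.weibull(0.9, 60) * 420)
        stat, p, _ = logrank_by_sex(self._records(f, m))
        pooled = np.concatenate([f, m])
        ones = np.ones(60)
        perm_stats = []
        for _ in range(1000):
            perm = rng.permutation(pooled)
            res = logrank_test(perm[:60], perm[60:], event_observed_A=ones, event_observed_B=ones)
            perm_stats.append(res.test_statistic)
        p_perm = float(np.mean(np.asarray(perm_stats) >= stat))
        mc_err = 3 * np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / 1000)
        assert abs(p - p_perm) < mc_err + 0.02


class TestEndToEnd:
    def test_generator_onsets_flow_through_cleaning(self, ingested):
        _, cohort, _, cfg, _ = ingested
        records, exclusions = compute_tto(cohort)
        assert all(r.onset_days >= 1 for r in records)
        assert len(records) + sum(exclusions.values()) == len(cohort)
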