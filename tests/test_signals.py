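"""Disproportionality statistics against hand-computed and simulated oracles."""

import math

import numpy as np
import pytest

from faerspv.signals import (
    ContingencyTable,
    UndefinedResultError,
    bcpnn_ic,
    compute_signal,
    detect,
    evaluate_signal,
    ic_raw,
    prr_chi2,
    ror,
)
from faerspv.synthetic import calibrate_cell_probs
from tests.conftest import make_case

T_REF = ContingencyTable(10, 90, 100, 9900)


class TestRor:
    def test_symmetric_table_is_null(self):
        est, lo, hi, _ = ror(ContingencyTable(10, 10, 10, 10))
        assert est == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_reference_table_arithmetic(self):
        est, lo, hi, se = ror(T_REF)
        assert est == pytest.approx(11.0)
        assert se == pytest.approx(math.sqrt(0.12121212121), rel=1e-6)
        assert lo == pytest.approx(5.56, abs=0.01)
        assert hi == pytest.approx(21.77, abs=0.01)

    def test_zero_cell_triggers_half_correction_flag(self):
        t = ContingencyTable(3, 0, 5, 100)
        cells, corrected = t.corrected_cells()
        assert corrected and cells == (3.5, 0.5, 5.5, 100.5)
        est, lo, hi, _ = ror(t)
        assert math.isfinite(est) and est == pytest.approx((3.5 * 100.5) / (0.5 * 5.5))

    def test_all_zero_table_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            ContingencyTable(0, 0, 0, 0)


class TestPrrChi2:
    def test_symmetric_table(self):
        prr, chi2 = prr_chi2(ContingencyTable(10, 10, 10, 10))
        assert (prr, chi2) == (1.0, 0.0)

    def test_reference_table(self):
        prr, chi2 = prr_chi2(T_REF)
        assert prr == pytest.approx(10.0)
        assert chi2 == pytest.approx(74.45, abs=0.01)

    def test_zero_a_gives_zero_prr(self):
        prr, _ = prr_chi2(ContingencyTable(0, 10, 10, 10000))
        assert prr == 0.0


class TestInformationComponent:
    def test_raw_ic_reference_value(self):
        assert ic_raw(T_REF) == pytest.approx(math.log2(101000 / 11000), rel=1e-12)
        assert ic_raw(T_REF) == pytest.approx(3.199, abs=5e-4)

    def test_independence_is_near_zero(self):
        t = ContingencyTable(10, 990, 990, 98010)  # expected a = 10 exactly
        assert abs(ic_raw(t)) < 1e-12
        ic, _ = bcpnn_ic(t)
        assert abs(ic) < 0.05

    def test_empty_joint_cell_is_finite_negative(self):
        ic, ic025 = bcpnn_ic(ContingencyTable(0, 10, 10, 10000))
        assert math.isfinite(ic) and ic < 0
        assert ic025 < ic


class TestEvaluateSignal:
    def test_reference_table_is_jointly_positive(self):
        r = compute_signal("x", "pt", T_REF)
        assert r.ror_positive and r.prr_positive and r.ic_positive and r.signal_positive

    def test_fewer_than_three_reports_never_signal(self):
        r = compute_signal("x", "pt", ContingencyTable(2, 5, 1, 10000))
        assert r.ror > 100  # huge effect size
        assert not r.signal_positive

    def test_prr_threshold_is_strict(self):
        # (c+d)/c = 20 with a/(a+b) = 0.1 makes PRR exactly 2
        r = compute_signal("x", "pt", ContingencyTable(10, 90, 50, 950))
        assert r.prr == pytest.approx(2.0)
        assert not r.prr_positive


class TestAlgebraicProperties:
    def test_ror_prr_consistency_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 5000, 4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            est, *_ = ror(t)
            prr, _ = prr_chi2(t)
            assert est / prr == pytest.approx((d / (c + d)) / (b / (a + b)), rel=1e-9)

    def test_statistics_monotone_in_a(self):
        prev = None
        for a in range(1, 40, 3):
            t = ContingencyTable(a, 500, 50, 5000)
            est, *_ = ror(t)
            prr, _ = prr_chi2(t)
            raw = ic_raw(t)
            if prev is not None:
                assert est >= prev[0] and prr >= prev[1] and raw >= prev[2]
            prev = (est, prr, raw)

    def test_ror_interval_covers_truth_at_nominal_rate(self):
        # tables simulated under a fixed true ROR; 95% CI coverage in [93%, 97%]
        true_ror = 3.0
        probs = calibrate_cell_probs(true_ror, 0.3, 0.05)
        rng = np.random.default_rng(7)
        tables = rng.multinomial(5000, probs, size=2000)
        covered = 0
        for a, b, c, d in tables:
            if min(a, b, c, d) == 0:
                continue
            _, lo, hi, _ = ror(ContingencyTable(int(a), int(b), int(c), int(d)))
            covered += lo <= true_ror <= hi
        assert 0.93 <= covered / len(tables) <= 0.97


class TestDetect:
    def test_repeated_pt_counts_once_per_report(self):
        cohort = [make_case(caseid=1, pts=["PT_X", "PT_X"])] + [
            make_case(caseid=i, pts=[]) for i in range(2, 12)
        ]
        background = [make_case(caseid=100 + i, pts=["PT_X"] if i < 3 else []) for i in range(50)]
        results, _ = detect(cohort, background)
        (res,) = [r for r in results if r.label == "PT_X"]
        assert res.table.a == 1

    def test_identical_composition_gives_no_flags(self):
        cohort = [make_case(caseid=i, pts=["PT_X"] if i % 10 == 0 else ["PT_Y"]) for i in range(1, 501)]
        background = [
            make_case(caseid=1000 + i, pts=["PT_X"] if i % 10 == 0 else ["PT_Y"])
            for i in range(1, 5001)
        ]
        results, _ = detect(cohort, background)
        assert not any(r.signal_positive for r in results)

    def test_soc_level_reports_unmapped_pts(self):
        cohort = [make_case(caseid=1, pts=["PT_KNOWN", "PT_MYSTERY"])]
        background = [make_case(caseid=2, pts=["PT_KNOWN"]), make_case(caseid=3, pts=[])]
        results, unmapped = detect(
            cohort, background, level="soc", pt_to_soc={"pt_known": "Some SOC"}
        )
        assert unmapped == {"PT_MYSTERY"}
        assert [r.label for r in results] == ["Some SOC"]

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            detect([make_case()], [])

    def test_results_sorted_by_descending_ror(self, ingested):
        _, cohort, background, _, _ = ingested
        results, _ = detect(cohort, background)
        rors = [r.ror for r in results]
        assert rors == sorted(rors, reverse=True)

    def test_configured_effects_flagged_nulls_not(self, ingested):
        _, cohort, background, cfg, truth = ingested
        results, _ = detect(cohort, background)
        by_label = {r.label: r for r in results}
        for name in truth.true_ror:
            if truth.true_ror[name]["overall"] >= 4:
                assert by_label[name].signal_positive, name
        null_flags = [
            r.signal_positive
            for r in results
            if r.label not in truth.true_ror and r.label != "Drug ineffective"
        ]
        assert sum(null_flags) <= 1  # at most one chance false positive
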