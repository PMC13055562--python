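"""Stratified detection, between-stratum ROR, FDR and volcano output."""

import math

import numpy as np
import pytest
from scipy import stats

from faerspv.signals import detect
from faerspv.subgroups import (
    between_group_ror,
    compare_strata,
    fdr_adjust,
    sex_stratum,
    shared_positive_pts,
    stratified_detect,
    therapy_stratum,
    volcano_table,
)
from tests.conftest import make_case


def _stratum_cases(n, n_with_pt, caseid_base=0, sex="F"):
    return [
        make_case(caseid=caseid_base + i, sex=sex, pts=["PT_X"] if i <= n_with_pt else [])
        for i in range(1, n + 1)
    ]


class TestBetweenGroupRor:
    def test_derived_arithmetic_example(self):
        a_cases = _stratum_cases(1000, 20)
        b_cases = _stratum_cases(1000, 10, caseid_base=5000, sex="M")
        comp = between_group_ror("PT_X", a_cases, b_cases)
        assert comp.ror == pytest.approx((20 * 990) / (980 * 10), rel=1e-12)
        # chi-square from the printed formula, p from its 1-df tail
        expected_chi2 = (20 * 990 - 980 * 10) ** 2 * 2000 / (1000 * 1000 * 30 * 1970)
        assert comp.chi2 == pytest.approx(expected_chi2, rel=1e-12)
        assert comp.p == pytest.approx(float(stats.chi2.sf(expected_chi2, 1)), rel=1e-12)

    def test_identical_frequency_is_null(self):
        a_cases = _stratum_cases(100, 10)
        b_cases = _stratum_cases(100, 10, caseid_base=5000, sex="M")
        comp = between_group_ror("PT_X", a_cases, b_cases)
        assert comp.ror == pytest.approx(1.0)
        assert comp.p == pytest.approx(1.0)

    def test_swapping_strata_inverts_ror_keeps_p(self):
        a_cases = _stratum_cases(1000, 20)
        b_cases = _stratum_cases(1000, 10, caseid_base=5000, sex="M")
        fwd = between_group_ror("PT_X", a_cases, b_cases)
        rev = between_group_ror("PT_X", b_cases, a_cases)
        assert rev.ror == pytest.approx(1.0 / fwd.ror, rel=1e-12)
        assert rev.p == pytest.approx(fwd.p, rel=1e-12)

    def test_case_order_is_irrelevant(self):
        a_cases = _stratum_cases(200, 15)
        b_cases = _stratum_cases(200, 5, caseid_base=5000, sex="M")
        fwd = between_group_ror("PT_X", a_cases, b_cases)
        rng = np.random.default_rng(0)
        shuffled = between_group_ror(
            "PT_X",
            [a_cases[i] for i in rng.permutation(len(a_cases))],
            [b_cases[i] for i in rng.permutation(len(b_cases))],
        )
        assert shuffled.ror == fwd.ror and shuffled.chi2 == fwd.chi2

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            between_group_ror("PT_X", [], _stratum_cases(10, 2))


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03]) == [0.03]

    def test_hand_computed_step_up(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones_stay_ones(self):
        assert fdr_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        p = rng.random(40)
        assert all(pa >= pr for pa, pr in zip(fdr_adjust(p), p))


class TestVolcano:
    def test_null_ror_maps_to_origin(self):
        a_cases = _stratum_cases(100, 10)
        b_cases = _stratum_cases(100, 10, caseid_base=5000, sex="M")
        table = volcano_table(compare_strata(["PT_X"], a_cases, b_cases))
        assert table.loc[0, "log2_ror"] == pytest.approx(0.0)
        assert table.loc[0, "direction"] == "none"

    def test_log_coordinates(self):
        a_cases = _stratum_cases(1000, 20)
        b_cases = _stratum_cases(1000, 10, caseid_base=5000, sex="M")
        comps = compare_strata(["PT_X"], a_cases, b_cases)
        comps[0].p_adj = 0.05
        table = volcano_table(comps)
        assert table.loc[0, "log2_ror"] == pytest.approx(1.0147, abs=1e-4)
        assert table.loc[0, "neg_log10_padj"] == pytest.approx(1.3010, abs=1e-4)

    def test_zero_padj_clamped_and_flagged(self):
        a_cases = _stratum_cases(1000, 20)
        b_cases = _stratum_cases(1000, 10, caseid_base=5000, sex="M")
        comps = compare_strata(["PT_X"], a_cases, b_cases)
        comps[0].p_adj = 0.0
        table = volcano_table(comps)
        assert bool(table.loc[0, "clamped"])
        assert math.isfinite(table.loc[0, "neg_log10_padj"])


class TestStratifiedDetect:
    def test_everyone_stratum_equals_unstratified(self, ingested):
        _, cohort, background, _, _ = ingested
        full, _ = detect(cohort, background)
        strat, _ = stratified_detect(cohort, background, lambda c: True)
        assert [(r.label, r.table.a, r.ror) for r in full] == [
            (r.label, r.table.a, r.ror) for r in strat
        ]

    def test_empty_stratum_returns_empty(self, ingested):
        _, cohort, background, _, _ = ingested
        results, unmapped = stratified_detect(cohort, background, lambda c: False)
        assert results == [] and unmapped == set()

    def test_sex_effect_shows_up_in_the_right_stratum(self, ingested):
        # generator default: lupus-like syndrome odds boosted in females
        _, cohort, background, _, truth = ingested
        f_res, _ = stratified_detect(cohort, background, sex_stratum("F"))
        m_res, _ = stratified_detect(cohort, background, sex_stratum("M"))
        f_ror = {r.label: r.ror for r in f_res}["Lupus-like syndrome"]
        m_ror = {r.label: r.ror for r in m_res}["Lupus-like syndrome"]
        assert f_ror > m_ror

    def test_therapy_stratum_partitions_cohort(self, ingested):
        _, cohort, _, _, _ = ingested
        mono = therapy_stratum("monotherapy")
        combo = therapy_stratum("combination")
        assert all(mono(c) != combo(c) for c in cohort)


class TestSharedSignals:
    def test_shared_positive_is_intersection(self, ingested):
        _, cohort, background, _, _ = ingested
        f_res, _ = stratified_detect(cohort, background, sex_stratum("F"))
        m_res, _ = stratified_detect(cohort, background, sex_stratum("M"))
        shared = shared_positive_pts(f_res, m_res)
        f_pos = {r.label for r in f_res if r.signal_positive}
        m_pos = {r.label for r in m_res if r.signal_positive}
        assert set(shared) == f_pos & m_pos
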