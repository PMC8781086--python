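"""Detection matching, glycaemic metrics, risk indices, CVGA, paired tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mealsense.detector import DetectionEvent
from mealsense.evaluation import (CVGA_SEVERITY, MatchResult,
                                  UndefinedMetricError, cvga_point,
                                  delay_summary, detection_report, fscore,
                                  glycaemic_summary, match_events,
                                  paired_compare, precision, recall,
                                  risk_indices)
from mealsense.scenario_sim import MealEvent


def _meals(onsets, slots=None):
    slots = slots or [0] * len(onsets)
    return [MealEvent(onset_min=o, true_grams=50.0, slot=s)
            for o, s in zip(onsets, slots)]


def _dets(times):
    return [DetectionEvent(flag_min=t) for t in times]


class TestMatchEvents:
    def test_worked_example(self):
        m = match_events(_meals([420, 780]), _dets([455, 1300]))
        assert (m.tp, m.fp, m.fn) == (1, 1, 1)
        assert m.delays_min == [35]

    def test_120_minute_rule(self):
        m = match_events(_meals([400]), _dets([530]))
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)
        m = match_events(_meals([400]), _dets([520]))
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_empty_detections(self):
        m = match_events(_meals([100, 200, 300]), [])
        assert (m.tp, m.fp, m.fn) == (0, 0, 3)

    def test_greedy_matches_optimal_bipartite(self):
        """Greedy chronological matching achieves the brute-force max TP."""
        rng = np.random.default_rng(7)
        for _ in range(60):
            n_m = rng.integers(1, 7)
            n_d = rng.integers(0, 7)
            meals = sorted(rng.integers(0, 2000, n_m).tolist())
            dets = sorted(rng.integers(0, 2000, n_d).tolist())
            got = match_events(_meals(meals), _dets(dets)).tp
            best = 0
            for k in range(min(n_m, n_d), -1, -1):
                for mc in itertools.combinations(range(n_m), k):
                    for dc in itertools.permutations(range(n_d), k):
                        if all(0 < dets[d] - meals[m] <= 120
                               for m, d in zip(mc, dc)):
                            best = max(best, k)
                    if best == k:
                        break
                if best:
                    break
            assert got == best


class TestRatios:
    def test_worked_examples(self):
        m = MatchResult(tp=9, fp=1, fn=3)
        assert precision(m) == pytest.approx(90.0)
        assert recall(m) == pytest.approx(75.0)
        assert fscore(m) == pytest.approx(0.818, abs=5e-4)

    def test_perfect_case(self):
        m = MatchResult(tp=5, fp=0, fn=0)
        assert (precision(m), recall(m), fscore(m)) == (100.0, 100.0, 1.0)

    def test_symmetric_92_gives_092(self):
        m = MatchResult(tp=92, fp=8, fn=8)
        assert precision(m) == pytest.approx(92.0)
        assert recall(m) == pytest.approx(92.0)
        assert fscore(m) == pytest.approx(0.92)

    def test_fscore_is_harmonic_mean_on_random_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = MatchResult(*rng.integers(1, 50, 3).tolist())
            p, r = precision(m) / 100, recall(m) / 100
            assert fscore(m) == pytest.approx(2 * p * r / (p + r), rel=1e-12)

    def test_zero_denominator_signals(self):
        with pytest.raises(UndefinedMetricError):
            precision(MatchResult(0, 0, 5))
        with pytest.raises(UndefinedMetricError):
            recall(MatchResult(0, 5, 0))


class TestGlycaemicSummary:
    def test_constant_in_range(self):
        gs = glycaemic_summary(np.full(100, 100.0))
        assert (gs.tir, gs.tar, gs.tbr, gs.mean_bg) == (100.0, 0.0, 0.0, 100.0)

    def test_boundary_180_counts_above(self):
        gs = glycaemic_summary(np.array([100.0, 200.0] * 50))
        assert gs.tir == 50.0 and gs.tar == 50.0
        gs = glycaemic_summary(np.array([100.0, 180.0]))
        assert gs.tar == 50.0

    def test_boundary_70_counts_below(self):
        gs = glycaemic_summary(np.full(10, 70.0))
        assert gs.tbr == 100.0

    @given(st.lists(st.floats(40, 400), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_ranges_partition_time(self, bg):
        gs = glycaemic_summary(np.asarray(bg))
        assert gs.tir + gs.tar + gs.tbr == pytest.approx(100.0, abs=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            glycaemic_summary(np.array([100.0, 0.0]))


class TestRiskIndices:
    def test_vanish_at_symmetrisation_root(self):
        root = float(np.exp(5.381 ** (1 / 1.084)))
        assert root == pytest.approx(112.5, abs=0.2)
        lbgi, hbgi, ri = risk_indices(np.full(10, root))
        assert abs(lbgi) < 1e-3 and abs(hbgi) < 1e-3

    def test_hypo_only_drives_lbgi(self):
        lbgi, hbgi, _ = risk_indices(np.full(10, 50.0))
        assert hbgi == 0.0 and lbgi > 0

    def test_ri_is_sum(self):
        rng = np.random.default_rng(2)
        bg = rng.uniform(50, 350, 500)
        lbgi, hbgi, ri = risk_indices(bg)
        assert ri == lbgi + hbgi


class TestCvga:
    @pytest.mark.parametrize("mn,mx,zone", [
        (110, 110, "A"),
        (95, 250, "UpperB"),
        (55, 170, "LowerC"),
        (80, 170, "LowerB"),
        (80, 250, "B"),
        (95, 330, "UpperC"),
        (80, 330, "UpperD"),
        (55, 250, "LowerD"),
        (55, 330, "E"),
    ])
    def test_zone_grid(self, mn, mx, zone):
        bg = np.array([float(mn), 120.0, float(mx)])
        assert cvga_point(bg).zone == zone

    def test_clamping(self):
        p = cvga_point(np.array([30.0, 500.0]))
        assert p.min_bg == 50.0 and p.max_bg == 400.0

    def test_monotone_severity(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            mn = rng.uniform(50, 110)
            mx = rng.uniform(110, 400)
            base = CVGA_SEVERITY[cvga_point(np.array([mn, mx])).zone]
            worse_min = CVGA_SEVERITY[cvga_point(np.array([mn - 10, mx])).zone]
            worse_max = CVGA_SEVERITY[cvga_point(np.array([mn, mx + 30])).zone]
            assert worse_min >= base
            assert worse_max >= base

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cvga_point(np.array([]))


class TestPairedCompare:
    def test_gaussian_shift_selects_t_test(self):
        rng = np.random.default_rng(4)
        a = rng.normal(100, 5, 12)
        b = a + 8.0 + rng.normal(0, 1, 12)
        res = paired_compare(a, b)
        assert res.test_name == "paired t-test"
        assert res.p_value < 0.05

    def test_skewed_differences_select_wilcoxon(self):
        rng = np.random.default_rng(5)
        a = np.full(25, 100.0)
        b = a + rng.lognormal(0, 1.5, 25)
        res = paired_compare(a, b)
        assert res.test_name == "wilcoxon"

    def test_bonferroni_threshold(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 10)
        res = paired_compare(a, a + rng.normal(2, 0.5, 10), n_comparisons=2)
        assert res.alpha == 0.025

    def test_degenerate_differences_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestDetectionReport:
    def test_snack_matches_not_charged_as_fp(self):
        meals = _meals([100, 500, 900], slots=[0, 2, 1])  # slot 2 is a snack
        dets = _dets([130, 530, 930])
        rep = detection_report(meals, dets, snack_slots=(2,))
        overall, m = rep["overall"], rep["meals"]
        assert (overall.tp, overall.fp, overall.fn) == (3, 0, 0)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_unmatched_detection_is_fp_in_both(self):
        rep = detection_report(_meals([100]), _dets([130, 1000]))
        assert rep["overall"].fp == 1 and rep["meals"].fp == 1

    def test_delay_summary_reports_median_and_mean(self):
        m = MatchResult(3, 0, 0, delays_min=[30.0, 40.0, 80.0])
        d = delay_summary(m)
        assert d["median"] == 40.0
        assert d["mean"] == pytest.approx(50.0)
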