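"""Detection and glycaemic-control metrics.

Detection: greedy chronological matching of flags to meals with a 120-min
true-positive window, then precision / recall / F-score and delay summaries.

Glycaemic control: time in range (70 < BG < 180 mg/dL), time above range
(BG >= 180), time below range (BG <= 70), mean glucose, the Kovatchev low /
high blood-glucose indices, and control-variability grid analysis (CVGA)
zoning of each subject's (minimum BG, maximum BG) pair.

Statistics: paired comparisons gated by a Shapiro-Wilk normality test on the
differences (paired t-test if normality is accepted at 0.05, Wilcoxon
signed-rank otherwise), with a Bonferroni-adjusted significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .detector import DetectionEvent
from .scenario_sim import MealEvent


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a ratio metric's denominator is zero."""


# ---------------------------------------------------------------------------
# detection metrics
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    delays_min: list[float] = field(default_factory=list)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(self.tp + other.tp, self.fp + other.fp,
                           self.fn + other.fn, self.delays_min + other.delays_min)


def match_events(true_meals: Sequence[MealEvent],
                 detections: Sequence[DetectionEvent],
                 max_delay_min: float = 120.0) -> MatchResult:
    """Greedy chronological one-to-one matching of detections to meals.

    A detection is a true positive when it falls within ``max_delay_min``
    after an unmatched meal's onset (it claims the most recent such meal).
    Unmatched detections are false positives; unmatched meals false negatives.
    Both inputs must be sorted in time.
    """
    meals = sorted(true_meals, key=lambda m: m.onset_min)
    dets = sorted(detections, key=lambda d: d.flag_min)
    claimed = [False] * len(meals)
    tp, fp = 0, 0
    delays: list[float] = []
    for det in dets:
        best = None
        for j, meal in enumerate(meals):
            if claimed[j]:
                continue
            delay = det.flag_min - meal.onset_min
            if 0 < delay <= max_delay_min:
                best = j  # keep scanning: later meals are more recent
            elif meal.onset_min >= det.flag_min:
                break
        if best is None:
            fp += 1
        else:
            claimed[best] = True
            det.matched_onset_min = meals[best].onset_min
            tp += 1
            delays.append(det.flag_min - meals[best].onset_min)
    fn = claimed.count(False)
    return MatchResult(tp=tp, fp=fp, fn=fn, delays_min=delays)


def precision(m: MatchResult) -> float:
    """TP / (TP + FP), as a percentage."""
    if m.tp + m.fp == 0:
        raise UndefinedMetricError("precision undefined: no detections")
    return 100.0 * m.tp / (m.tp + m.fp)


def recall(m: MatchResult) -> float:
    """TP / (TP + FN), as a percentage."""
    if m.tp + m.fn == 0:
        raise UndefinedMetricError("recall undefined: no meals")
    return 100.0 * m.tp / (m.tp + m.fn)


def fscore(m: MatchResult) -> float:
    """Harmonic mean of precision and recall, as a fraction in [0, 1]."""
    p, r = precision(m), recall(m)
    if p + r == 0:
        raise UndefinedMetricError("F-score undefined: precision + recall = 0")
    return 2.0 * (p / 100.0) * (r / 100.0) / ((p + r) / 100.0)


def delay_summary(m: MatchResult) -> dict[str, float]:
    """Median (primary) plus mean +/- SD of true-positive detection delays."""
    if not m.delays_min:
        return {"median": float("nan"), "mean": float("nan"), "sd": float("nan")}
    d = np.asarray(m.delays_min)
    return {"median": float(np.median(d)), "mean": float(d.mean()),
            "sd": float(d.std(ddof=1)) if len(d) > 1 else 0.0}


# ---------------------------------------------------------------------------
# glycaemic metrics
# ---------------------------------------------------------------------------

@dataclass
class GlycaemicSummary:
    mean_bg: float
    tir: float
    tar: float
    tbr: float
    lbgi: float
    hbgi: float
    ri: float


def risk_indices(bg: np.ndarray) -> tuple[float, float, float]:
    """Kovatchev LBGI / HBGI / RI via the symmetrising log transform.

    f(BG) = 1.509 * ((ln BG)^1.084 - 5.381); risk = 10 f^2, split by sign.
    Both indices vanish at the symmetrisation root, BG ~ 112.5 mg/dL.
    """
    bg = np.asarray(bg, dtype=float)
    if bg.size == 0 or np.any(bg <= 0):
        raise ValueError("blood glucose series must be positive and non-empty")
    f = 1.509 * (np.log(bg) ** 1.084 - 5.381)
    risk = 10.0 * f * f
    lbgi = float(np.mean(np.where(f < 0, risk, 0.0)))
    hbgi = float(np.mean(np.where(f > 0, risk, 0.0)))
    return lbgi, hbgi, lbgi + hbgi


def glycaemic_summary(bg: np.ndarray) -> GlycaemicSummary:
    """Time-in-ranges and risk indices; TAR includes 180, TBR includes 70."""
    bg = np.asarray(bg, dtype=float)
    if bg.size == 0 or np.any(bg <= 0):
        raise ValueError("blood glucose series must be positive and non-empty")
    tar = 100.0 * np.mean(bg >= 180.0)
    tbr = 100.0 * np.mean(bg <= 70.0)
    tir = 100.0 * np.mean((bg > 70.0) & (bg < 180.0))
    lbgi, hbgi, ri = risk_indices(bg)
    return GlycaemicSummary(mean_bg=float(bg.mean()), tir=float(tir),
                            tar=float(tar), tbr=float(tbr),
                            lbgi=lbgi, hbgi=hbgi, ri=ri)


# ---------------------------------------------------------------------------
# CVGA
# ---------------------------------------------------------------------------

#: zone ordering for monotonicity checks (A best, E worst)
CVGA_SEVERITY = {"A": 0, "UpperB": 1, "LowerB": 1, "B": 1,
                 "UpperC": 2, "LowerC": 2, "UpperD": 3, "LowerD": 3, "E": 4}


@dataclass
class CvgaPoint:
    min_bg: float   # clamped to [50, 110]
    max_bg: float   # clamped to [110, 400]
    zone: str


def cvga_point(bg: np.ndarray) -> CvgaPoint:
    """Classify one subject's assessment period onto the CVGA grid.

    The point is (min BG, max BG), clamped to the grid's [50, 110] x
    [110, 400] frame.  Zone boundaries (min-BG bands >= 90 / 70-90 / < 70;
    max-BG bands <= 180 / 180-300 / > 300):

        max <= 180:        A       | LowerB  | LowerC
        180 < max <= 300:  UpperB  | B       | LowerD
        max > 300:         UpperC  | UpperD  | E

    Lower zones are reached by worsening minima (hypoglycaemia exposure),
    Upper zones by worsening maxima (hyperglycaemia exposure); LowerD marks
    failure to deal with hypoglycaemia during otherwise ordinary control.
    The zone ordering A < B < C < D < E is monotone in both axes: lowering
    the minimum or raising the maximum never improves the zone.
    """
    bg = np.asarray(bg, dtype=float)
    if bg.size == 0:
        raise ValueError("empty glucose series")
    mn = float(np.clip(bg.min(), 50.0, 110.0))
    mx = float(np.clip(bg.max(), 110.0, 400.0))
    col = 0 if mn >= 90 else (1 if mn >= 70 else 2)
    row = 0 if mx <= 180 else (1 if mx <= 300 else 2)
    grid = [["A", "LowerB", "LowerC"],
            ["UpperB", "B", "LowerD"],
            ["UpperC", "UpperD", "E"]]
    return CvgaPoint(min_bg=mn, max_bg=mx, zone=grid[row][col])


# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------

@dataclass
class PairedTestResult:
    p_value: float
    test_name: str             # "paired t-test" or "wilcoxon"
    alpha: float               # Bonferroni-adjusted significance threshold
    statistic: float
    shapiro_p: float


def paired_compare(metric_a: Sequence[float], metric_b: Sequence[float],
                   n_comparisons: int = 1) -> PairedTestResult:
    """Paired comparison with normality-gated test choice.

    Shapiro-Wilk on the paired differences at 0.05 selects between a paired
    t-test (normality accepted) and the Wilcoxon signed-rank test.  The
    reported alpha is 0.05 / n_comparisons.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length paired samples with n >= 3")
    diff = b - a
    if np.allclose(diff, 0.0):
        raise ValueError("all paired differences are zero; comparison is degenerate")
    shapiro_p = float(sps.shapiro(diff).pvalue)
    if shapiro_p >= 0.05:
        res = sps.ttest_rel(b, a)
        name = "paired t-test"
    else:
        res = sps.wilcoxon(b, a)
        name = "wilcoxon"
    return PairedTestResult(p_value=float(res.pvalue), test_name=name,
                            alpha=0.05 / n_comparisons,
                            statistic=float(res.statistic), shapiro_p=shapiro_p)


# ---------------------------------------------------------------------------
# meals-only detection report
# ---------------------------------------------------------------------------

def detection_report(true_meals: Sequence[MealEvent],
                     detections: Sequence[DetectionEvent],
                     snack_slots: Sequence[int] = (2,),
                     max_delay_min: float = 120.0) -> dict:
    """Precision/recall/F for all events and for meals only (snacks excluded).

    For the meals-only figures, detections are first matched against all
    events so that a flag explained by a snack is not charged as a false
    positive; TP/FN are then restricted to non-snack meals.
    """
    overall = match_events(true_meals, detections, max_delay_min)
    snack_onsets = {m.onset_min for m in true_meals if m.slot in snack_slots}
    tp_meals, fp = 0, 0
    delays: list[float] = []
    for det in detections:
        if det.matched_onset_min is None:
            fp += 1
        elif det.matched_onset_min not in snack_onsets:
            tp_meals += 1
            delays.append(det.flag_min - det.matched_onset_min)
    n_meals = sum(1 for m in true_meals if m.slot not in snack_slots)
    meals = MatchResult(tp=tp_meals, fp=fp, fn=n_meals - tp_meals, delays_min=delays)
    return {"overall": overall, "meals": meals}
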