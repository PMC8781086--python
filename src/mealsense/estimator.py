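"""Carbohydrate estimation by inverse-input search.

Once a meal flag is active, candidate meal sizes are injected into the
forecaster's carbohydrate input at the inferred meal onset and the median
forecast is compared with the observed CGM.  The search is coarse-to-fine:
10 g increments until the absolute error at the present sample drops below a
threshold epsilon (the fine-tuned model's validation MAE), then a 1 g walk
restarted from one coarse step back.  Estimates are capped at 90 g; if
adding carbohydrate fails to reduce the error the candidate violates the
expected physiological dynamics and the meal is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .forecaster import ModelBundle, WindowBatch, predict_batch

M_MAX = 90.0
COARSE_STEP = 10.0
FINE_STEP = 1.0


@dataclass(frozen=True)
class EpsilonThreshold:
    """Deviation threshold: the per-individual validation MAE (mg/dL)."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("epsilon cannot be negative")


@dataclass
class EstimationResult:
    grams: float
    final_error: float
    iterations: int
    capped: bool = False
    discarded: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.grams <= M_MAX:
            raise ValueError("estimated grams must lie in [0, 90]")
        if self.discarded and self.grams != 0:
            raise ValueError("a discarded estimate must carry 0 grams")


def compute_epsilon(targets: Sequence[float],
                    median_predictions: Sequence[float]) -> EpsilonThreshold:
    """Mean absolute error between reference glucose and median predictions."""
    y = np.asarray(targets, dtype=float)
    yh = np.asarray(median_predictions, dtype=float)
    if y.size == 0 or y.shape != yh.shape:
        raise ValueError("series must be non-empty and of equal length")
    return EpsilonThreshold(float(np.mean(np.abs(y - yh))))


def verify_dynamics(error_trace: Sequence[float]) -> bool:
    """Check that the last coarse increment moved the forecast toward the CGM.

    Returns False (discard the meal) when the error is non-decreasing across
    the two most recent coarse iterations: more carbohydrate should produce a
    higher trajectory, so a flat or rising error means the flagged deviation
    is not meal-like.
    """
    if len(error_trace) < 2:
        raise ValueError("need at least two coarse iterations to verify dynamics")
    return error_trace[-1] < error_trace[-2]


def search_meal_size(response: Callable[[float], float], cgm_now: float,
                     epsilon: EpsilonThreshold) -> EstimationResult:
    """Coarse/fine search over candidate grams given a median-response function.

    ``response(grams)`` must return the model's median glucose prediction at
    the present sample with ``grams`` injected at the inferred meal onset.
    """
    if epsilon.value <= 0:
        raise ValueError("epsilon must be positive; a zero threshold is degenerate")

    def err(m: float) -> float:
        return abs(float(response(m)) - cgm_now)

    iterations = 1
    trace = [err(0.0)]
    if trace[0] <= epsilon.value:
        return EstimationResult(0.0, trace[0], iterations)

    m = 0.0
    while m < M_MAX:
        m += COARSE_STEP
        e = err(m)
        iterations += 1
        trace.append(e)
        if e <= epsilon.value:
            break
        if not verify_dynamics(trace):
            return EstimationResult(0.0, e, iterations, discarded=True)
    else:  # pragma: no cover - loop always exits via break or m reaching M_MAX
        pass
    if trace[-1] > epsilon.value:
        return EstimationResult(M_MAX, trace[-1], iterations, capped=True)

    # fine phase: rerun from one coarse step back in 1 g increments
    base = m - COARSE_STEP
    f = base
    while f < m:
        f += FINE_STEP
        e = err(f)
        iterations += 1
        if e <= epsilon.value:
            return EstimationResult(float(f), e, iterations)
    return EstimationResult(float(m), trace[-1], iterations)


def estimate_meal(bundle: ModelBundle | Callable[[float], float],
                  window: WindowBatch | None, cgm_now: float,
                  epsilon: EpsilonThreshold,
                  inject_pos: int = -1) -> EstimationResult:
    """Estimate the grams of an unannounced meal behind an active flag.

    ``window`` is the raw forecast window ending at the flagged sample;
    candidate grams are added to its encoder carbohydrate channel at
    ``inject_pos`` (default: the final encoder step, 20 min before now, the
    onset implied by the persistence rule).  ``bundle`` may alternatively be a
    callable ``grams -> median glucose`` (e.g. a stub model), in which case
    ``window`` is ignored.
    """
    if callable(bundle) and not isinstance(bundle, ModelBundle):
        return search_meal_size(bundle, cgm_now, epsilon)
    if window is None or len(window) != 1:
        raise ValueError("estimate_meal expects a single forecast window")

    base_enc = window.enc.copy()

    def response(grams: float) -> float:
        enc = base_enc.copy()
        enc[0, inject_pos, 2] += grams
        wb = WindowBatch(enc, window.dec, window.targets, window.stats or bundle.stats)
        return float(predict_batch(bundle, wb)[0, -1, 1])

    return search_meal_size(response, cgm_now, epsilon)
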