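"""Prediction-interval meal detection.

A meal flag is raised when the CGM exceeds the forecast's upper quantile for
more than N consecutive samples (N = 2, i.e. flag on the third sample, 15 min
after the first exceedance) while glucose is rising at >= 1 mg/dL/min.  The
persistence rule guards against transient sensor noise; the rate-of-change
rule guards against slow drifts that are not meal-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forecaster import QuantileForecast
from .scenario_sim import STEP_MIN


@dataclass(frozen=True)
class DetectorConfig:
    persistence_n: int = 2          # flag when k > N
    roc_threshold: float = 1.0      # mg/dL/min
    roc_window: int = 3             # CGM samples used for the slope
    refractory_min: float = 60.0    # quiet period after an accepted estimate

    def __post_init__(self) -> None:
        if self.persistence_n < 0:
            raise ValueError("persistence_n must be >= 0")
        if self.roc_threshold < 0:
            raise ValueError("roc_threshold must be >= 0")
        if self.roc_window < 2:
            raise ValueError("roc_window must be >= 2")


@dataclass
class DetectionState:
    """Mutable per-subject detector state carried across samples."""

    k: int = 0                           # consecutive upper-bound exceedances
    first_exceed_min: float | None = None
    last_accept_min: float | None = None  # time of last accepted estimate


@dataclass
class DetectionEvent:
    flag_min: float
    estimated_grams: float = 0.0
    k_at_flag: int = 0
    roc: float = 0.0
    discarded: bool = False
    capped: bool = False
    matched_onset_min: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.estimated_grams <= 90:
            raise ValueError("estimated grams must lie in [0, 90]")


def rate_of_change(cgm: np.ndarray, step_min: float = STEP_MIN) -> float:
    """Least-squares slope of recent CGM samples, in mg/dL/min."""
    cgm = np.asarray(cgm, dtype=float)
    if len(cgm) < 2:
        raise ValueError("rate_of_change needs at least 2 samples")
    t = step_min * np.arange(len(cgm))
    return float(np.polyfit(t, cgm, 1)[0])


def update_detector(state: DetectionState, forecast: QuantileForecast,
                    cgm_now: float, roc: float, config: DetectorConfig,
                    now_min: float) -> tuple[DetectionState, bool]:
    """Process one CGM sample; returns the updated state and the flag.

    The forecast's final decoder step is the one aligned with ``cgm_now``.
    The exceedance counter increments while CGM sits above the upper bound and
    resets the moment it falls back inside.  The flag requires k > N, the
    rate-of-change condition, and being outside the refractory window of the
    last accepted estimate.
    """
    upper_now = float(forecast.upper[-1])
    if cgm_now > upper_now:
        if state.k == 0:
            state.first_exceed_min = now_min
        state.k += 1
    else:
        state.k = 0
        state.first_exceed_min = None
    in_refractory = (state.last_accept_min is not None
                     and now_min - state.last_accept_min < config.refractory_min)
    flag = (state.k > config.persistence_n
            and roc >= config.roc_threshold
            and not in_refractory)
    return state, flag
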