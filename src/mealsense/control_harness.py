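"""Closed-loop insulin delivery harness.

Wires the surrogate simulator, the quantile forecaster, the meal detector and
the carbohydrate estimator to a generic basal-bolus controller in three
configurations:

* ``nma`` - no meal announcement: feedback basal modulation only (fully
  closed loop, the floor configuration);
* ``md``  - meal detection: nma plus automatic meal boluses from the
  detection/estimation module (fully closed loop);
* ``ma``  - meal announcement: user announcements (with the behaviour model's
  skips, delays and carb-counting errors) drive boluses at announcement time
  (hybrid closed loop).

The feedback layer is a clamped proportional-derivative modulation of the
basal rate around a glucose target; the detection/estimation algorithm is
agnostic to this choice of controller.  An automatic meal bolus is weighted
by W = 0.5, carries no correction component, and suspends basal delivery for
one hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detector import (DetectionEvent, DetectionState, DetectorConfig,
                       rate_of_change, update_detector)
from .estimator import EpsilonThreshold, estimate_meal
from .forecaster import ModelBundle, QuantileForecast, WindowBatch, predict_batch
from .scenario_sim import (STEP_MIN, GlucoseTimeline, SubjectScenario,
                           SubjectSimulator)

MODES = ("nma", "md", "ma")


@dataclass(frozen=True)
class ControllerConfig:
    carb_ratio: float = 10.0          # g/U
    correction_factor: float = 40.0   # (mg/dL)/U
    target: float = 120.0             # mg/dL
    meal_bolus_weight: float = 0.5    # W applied to automatic meal boluses
    basal_suspension_min: float = 60.0
    mode: str = "md"
    # feedback layer: basal = nominal + kp*(G - target) + kd*dG/dt, clamped
    kp: float = 0.015                 # (U/h) per mg/dL
    kd: float = 0.5                   # (U/h) per (mg/dL/min)
    basal_clamp_factor: float = 3.0   # max basal as multiple of nominal

    def __post_init__(self) -> None:
        if not 0 <= self.meal_bolus_weight <= 1:
            raise ValueError("meal bolus weight W must lie in [0, 1]")
        if self.basal_suspension_min < 0:
            raise ValueError("basal suspension must be non-negative")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class LoopRecord:
    """Per-run log of what the controller did and why."""

    mode: str
    detections: list[DetectionEvent] = field(default_factory=list)
    meal_bolus_steps: list[int] = field(default_factory=list)
    meal_bolus_units: list[float] = field(default_factory=list)


def meal_bolus(grams: float, config: ControllerConfig) -> float:
    """Weighted meal bolus W * grams / ICR; no correction component."""
    if grams < 0:
        raise ValueError("grams must be non-negative")
    return config.meal_bolus_weight * grams / config.carb_ratio


def _feedback_basal(nominal: float, glucose: float, roc: float,
                    config: ControllerConfig) -> float:
    basal = nominal + config.kp * (glucose - config.target) + config.kd * roc
    return float(np.clip(basal, 0.0, config.basal_clamp_factor * nominal))


def run_closed_loop(scenario: SubjectScenario, bundle: ModelBundle | None,
                    detector_config: DetectorConfig,
                    controller_config: ControllerConfig,
                    ) -> tuple[GlucoseTimeline, LoopRecord]:
    """Step the simulator at 5 min under the configured control mode.

    ``bundle`` is required for ``md`` mode only.  Detection at sample t uses a
    forecast window ending at t (the model never sees the last 20 min of CGM);
    an accepted estimate delivers its weighted bolus at t+1, suspends basal
    for the following 12 steps, and writes the estimated grams into the
    announced-carbohydrate channel at the inferred onset so that subsequent
    forecasts explain the excursion.
    """
    mode = controller_config.mode
    if mode == "md" and bundle is None:
        raise ValueError("md mode requires a trained model bundle")
    sim = SubjectSimulator(scenario.params, scenario.events, scenario.days,
                           scenario.seed, scenario.cgm_noise_sd, scenario.cgm_noise_ar)
    n = sim.n_steps
    nominal = scenario.params.basal_rate

    glucose = np.empty(n)
    true_g = np.empty(n)
    basal = np.zeros(n)
    bolus = np.zeros(n)
    carbs = np.zeros(n)
    announced = np.zeros(n)
    for ev in scenario.events:
        carbs[ev.onset_min // STEP_MIN] += ev.true_grams

    ma_bolus = np.zeros(n)
    if mode == "ma":
        for ev in scenario.events:
            if ev.announced:
                step = min(ev.announcement_min // STEP_MIN, n - 1)
                ma_bolus[step] += ev.announced_grams / controller_config.carb_ratio
                announced[step] += ev.announced_grams

    enc_len = bundle.config.enc_len if bundle is not None else 24
    epsilon = EpsilonThreshold(bundle.validation_mae) if mode == "md" else None
    state = DetectionState()
    record = LoopRecord(mode=mode)
    pending_bolus = 0.0
    suspend_until = 0  # first step index no longer suspended
    roc_w = detector_config.roc_window

    for i in range(n):
        g_latest = glucose[i - 1] if i > 0 else sim.G
        roc_fb = rate_of_change(glucose[max(0, i - roc_w):i]) if i >= 2 else 0.0
        b = _feedback_basal(nominal, g_latest, roc_fb, controller_config)
        if i < suspend_until:
            b = 0.0
        u = pending_bolus + ma_bolus[i]
        pending_bolus = 0.0
        basal[i], bolus[i] = b, u
        glucose[i], true_g[i] = sim.step(b, u)

        if mode != "md" or i < enc_len + 3:
            continue
        a = i - enc_len - 3
        seg = slice(a, i + 1)
        ins = basal[seg] * (STEP_MIN / 60.0) + bolus[seg]
        feats = np.stack([glucose[seg], ins, announced[seg]], axis=1)
        window = WindowBatch(enc=feats[None, :enc_len, :],
                             dec=feats[None, enc_len:, 1:],
                             targets=glucose[seg][None, enc_len:],
                             stats=bundle.stats)
        pred = predict_batch(bundle, window)[0]
        forecast = QuantileForecast(lower=pred[:, 0], median=pred[:, 1], upper=pred[:, 2])
        roc = rate_of_change(glucose[i - roc_w + 1:i + 1])
        now_min = i * STEP_MIN
        state, flag = update_detector(state, forecast, glucose[i], roc,
                                      detector_config, now_min)
        if not flag:
            continue
        result = estimate_meal(bundle, window, glucose[i], epsilon)
        record.detections.append(DetectionEvent(
            flag_min=now_min, estimated_grams=result.grams, k_at_flag=state.k,
            roc=roc, discarded=result.discarded, capped=result.capped))
        if not result.discarded and result.grams > 0:
            dose = meal_bolus(result.grams, controller_config)
            pending_bolus += dose
            suspend_steps = int(round(controller_config.basal_suspension_min / STEP_MIN))
            suspend_until = i + 1 + suspend_steps
            state.last_accept_min = now_min
            announced[i - 4] += result.grams  # inferred onset: final encoder step
            record.meal_bolus_steps.append(i + 1)
            record.meal_bolus_units.append(dose)
        state.k = 0
        state.first_exceed_min = None

    timeline = GlucoseTimeline(glucose=glucose, true_glucose=true_g, basal=basal,
                               bolus=bolus, carbs=carbs, announced_carbs=announced)
    return timeline, record
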