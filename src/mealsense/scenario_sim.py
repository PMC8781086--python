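"""Surrogate type 1 diabetes simulator.

Generates CGM/insulin/meal timelines with the statistical structure of the
evaluation scenario: four daily meals (70/100/30/80 g at 07:00/13:00/17:00/20:00,
meal-time SD 60 min, size CV 10%), sinusoidal intra-day insulin-sensitivity
variability, per-day insulin-absorption variability of +/-30%, carb-counting
error uniform on [-30%, +10%], and on average 2.5 skipped plus 2 delayed meal
announcements per week.

The physiology engine is a Bergman-style minimal model augmented with a
two-compartment gut-absorption cascade (rate-of-appearance peak at the carb
absorption time, default 40 min) and a two-compartment subcutaneous insulin
depot (absorption peak at the insulin action time, default 55 min).  It is a
deliberately small surrogate: rich enough to produce realistic postprandial
excursions for a meal detector to find, not a replacement for a full
physiological simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

#: global CGM sampling step, minutes
STEP_MIN = 5
STEPS_PER_DAY = 24 * 60 // STEP_MIN
#: internal Euler integration step, minutes
_ODE_DT = 1.0


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectParams:
    """Physiological parameters of one simulated subject.

    ``body_glucose_setpoint`` is the equilibrium glucose of the model in the
    absence of insulin (endogenous production balance); basal insulin pulls
    fasting glucose below it.  ``insulin_sensitivity_base`` is the total
    glucose-lowering effect of one unit of insulin (mg/dL per U), i.e. the
    correction factor; the per-gram glucose rise is tied to it through the
    carb ratio so that one unit covers ``carb_ratio`` grams.
    """

    basal_rate: float = 0.47            # U/h, nominal open-loop basal
    insulin_sensitivity_base: float = 40.0   # (mg/dL)/U
    carb_ratio: float = 10.0            # g/U
    glucose_effectiveness: float = 0.005     # 1/min
    insulin_action_time: float = 55.0   # min, SC absorption peak
    carb_absorption_time: float = 40.0  # min, gut absorption peak
    remote_action_time: float = 40.0    # min, lag of remote insulin action
    body_glucose_setpoint: float = 160.0     # mg/dL, zero-insulin equilibrium
    si_sin_amplitude: float = 0.30      # fraction of base sensitivity
    si_sin_period: float = 24.0         # h
    si_sin_phase: float = 0.0           # h
    insulin_absorption_var: float = 0.30     # fraction, per-day U[1-v, 1+v]

    def __post_init__(self) -> None:
        for name in ("basal_rate", "insulin_sensitivity_base", "carb_ratio",
                     "glucose_effectiveness", "insulin_action_time",
                     "carb_absorption_time", "remote_action_time",
                     "body_glucose_setpoint"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.si_sin_amplitude < 1:
            raise ValueError("si_sin_amplitude must be in [0, 1)")
        if not 0 <= self.insulin_absorption_var < 1:
            raise ValueError("insulin_absorption_var must be in [0, 1)")

    @property
    def carb_gain(self) -> float:
        """Total glucose rise per gram of carbohydrate (mg/dL/g).

        Chosen so that one unit of insulin (lowering ``insulin_sensitivity``
        mg/dL) exactly covers ``carb_ratio`` grams.
        """
        return self.insulin_sensitivity_base / self.carb_ratio

    def insulin_sensitivity_at(self, t_min: float) -> float:
        """Sinusoidally modulated insulin sensitivity at time t (minutes)."""
        omega = 2.0 * np.pi / (self.si_sin_period * 60.0)
        return self.insulin_sensitivity_base * (
            1.0 + self.si_sin_amplitude * np.sin(omega * (t_min - self.si_sin_phase * 60.0))
        )

    def fasting_glucose(self, basal_uhr: float | None = None) -> float:
        """Closed-form fasting equilibrium under a constant basal rate."""
        ub = self.basal_rate if basal_uhr is None else basal_uhr
        x_ss = self.insulin_sensitivity_base * ub / 60.0  # mg/dL/min
        sg, gb = self.glucose_effectiveness, self.body_glucose_setpoint
        # SG*(G-Gb) + X*G/Gb = 0  ->  G = SG*Gb / (SG + X/Gb)
        return sg * gb / (sg + x_ss / gb)

    def equilibrium_basal(self, target_glucose: float = 115.0) -> float:
        """Basal rate (U/h) that holds fasting glucose at ``target_glucose``."""
        sg, gb = self.glucose_effectiveness, self.body_glucose_setpoint
        if not 0 < target_glucose < gb:
            raise ValueError("target must lie below the zero-insulin setpoint")
        x_ss = sg * (gb - target_glucose) * gb / target_glucose
        return 60.0 * x_ss / self.insulin_sensitivity_base


@dataclass(frozen=True)
class MealProtocol:
    """Daily meal slots: mean sizes (g), mean clock times (min), variability."""

    mean_sizes: tuple[float, ...] = (70.0, 100.0, 30.0, 80.0)
    mean_times: tuple[float, ...] = (7 * 60.0, 13 * 60.0, 17 * 60.0, 20 * 60.0)
    time_sd: float = 60.0   # min
    size_cv: float = 0.10   # fraction
    #: slot indices counted as snacks (excluded from meals-only metrics)
    snack_slots: tuple[int, ...] = (2,)

    def __post_init__(self) -> None:
        if len(self.mean_sizes) != len(self.mean_times):
            raise ValueError("mean_sizes and mean_times must align")
        if any(s <= 0 for s in self.mean_sizes):
            raise ValueError("meal sizes must be positive")
        if list(self.mean_times) != sorted(self.mean_times):
            raise ValueError("meal slots must be ordered by clock time")
        if self.time_sd < 0 or self.size_cv < 0:
            raise ValueError("variability parameters must be non-negative")

    @property
    def n_slots(self) -> int:
        return len(self.mean_sizes)


@dataclass(frozen=True)
class BehaviourParams:
    """Announcement behaviour: skipped/delayed boluses and carb-counting error."""

    skip_rate: float = 2.5     # announcements skipped per week
    delay_rate: float = 2.0    # announcements delayed per week
    delay_low: float = 15.0    # min, uniform delay lower bound
    delay_high: float = 60.0   # min, uniform delay upper bound
    carb_error_low: float = -0.30
    carb_error_high: float = 0.10

    def __post_init__(self) -> None:
        if self.skip_rate < 0 or self.delay_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.carb_error_low > self.carb_error_high:
            raise ValueError("carb_error_low must be <= carb_error_high")
        if not 0 <= self.delay_low <= self.delay_high:
            raise ValueError("delay bounds must satisfy 0 <= low <= high")

    @classmethod
    def ideal(cls) -> "BehaviourParams":
        """No skips, no delays, exact carb counting."""
        return cls(skip_rate=0.0, delay_rate=0.0, delay_low=0.0, delay_high=0.0,
                   carb_error_low=0.0, carb_error_high=0.0)


@dataclass
class MealEvent:
    """One ground-truth meal, with its (possibly absent) announcement."""

    onset_min: int            # minutes from scenario start
    true_grams: float
    announced_grams: float | None = None
    announcement_min: int | None = None
    slot: int = 0             # index into the protocol's meal slots

    def __post_init__(self) -> None:
        if self.true_grams <= 0:
            raise ValueError("true_grams must be positive")
        if self.announcement_min is not None and self.announcement_min < self.onset_min - 60:
            raise ValueError("announcement cannot precede onset by more than 60 min")

    @property
    def announced(self) -> bool:
        return self.announced_grams is not None


@dataclass
class GlucoseTimeline:
    """Aligned 5-min series of CGM, insulin, and carbohydrate intake."""

    glucose: np.ndarray          # mg/dL, CGM (noisy)
    true_glucose: np.ndarray     # mg/dL, plasma glucose
    basal: np.ndarray            # U/h commanded per step
    bolus: np.ndarray            # U delivered in the step
    carbs: np.ndarray            # g ingested in the step (ground truth)
    announced_carbs: np.ndarray  # g announced/estimated at the step
    start_min: int = 0
    step_min: int = STEP_MIN

    def __post_init__(self) -> None:
        n = len(self.glucose)
        for name in ("true_glucose", "basal", "bolus", "carbs", "announced_carbs"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name} length mismatch")
        if (24 * 60) % self.step_min != 0:
            raise ValueError("step must divide 24 h")
        if np.any(self.glucose <= 0):
            raise ValueError("CGM glucose must be positive throughout")

    def __len__(self) -> int:
        return len(self.glucose)

    @property
    def times_min(self) -> np.ndarray:
        return self.start_min + self.step_min * np.arange(len(self))

    @property
    def insulin_per_step(self) -> np.ndarray:
        """Total insulin delivered in each 5-min step (U): basal share + bolus."""
        return self.basal * (self.step_min / 60.0) + self.bolus

    def slice_steps(self, a: int, b: int) -> "GlucoseTimeline":
        return GlucoseTimeline(
            glucose=self.glucose[a:b], true_glucose=self.true_glucose[a:b],
            basal=self.basal[a:b], bolus=self.bolus[a:b], carbs=self.carbs[a:b],
            announced_carbs=self.announced_carbs[a:b],
            start_min=self.start_min + a * self.step_min, step_min=self.step_min)


@dataclass
class SubjectScenario:
    """Everything needed to reproduce one simulated subject."""

    params: SubjectParams
    events: list[MealEvent]
    days: int
    seed: int
    cgm_noise_sd: float = 7.0
    cgm_noise_ar: float = 0.7


# ---------------------------------------------------------------------------
# scenario sampling
# ---------------------------------------------------------------------------

def sample_scenario(protocol: MealProtocol, behaviour: BehaviourParams,
                    days: int, seed: int) -> list[MealEvent]:
    """Sample ground-truth meals and announcement behaviour for ``days`` days.

    Each day has one meal per protocol slot.  Onsets are slot mean +
    Normal(0, time_sd), resampled as a day if the daily ordering is violated;
    sizes are Normal(mean, cv*mean) truncated positive.  Skips and delays are
    Bernoulli per event with weekly expectations matching the behaviour rates;
    announced grams carry a uniform carb-counting error.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    n_slots = protocol.n_slots
    events_per_week = 7 * n_slots
    p_skip = min(1.0, behaviour.skip_rate / events_per_week)
    p_delay = min(1.0, behaviour.delay_rate / events_per_week)

    events: list[MealEvent] = []
    for day in range(days):
        # resample the whole day until slot ordering holds and times fit the day
        for _ in range(1000):
            times = np.asarray(protocol.mean_times) + rng.normal(0.0, protocol.time_sd, n_slots)
            if np.all(np.diff(times) > 0) and times[0] >= 0 and times[-1] < 24 * 60:
                break
        else:  # pragma: no cover - essentially impossible with sane protocols
            times = np.asarray(protocol.mean_times, dtype=float)
        for slot in range(n_slots):
            mean = protocol.mean_sizes[slot]
            grams = rng.normal(mean, protocol.size_cv * mean)
            while grams <= 0:
                grams = rng.normal(mean, protocol.size_cv * mean)
            onset = int(round(day * 24 * 60 + times[slot]))
            skipped = rng.random() < p_skip
            delayed = (not skipped) and rng.random() < p_delay
            if skipped:
                ann_g, ann_t = None, None
            else:
                err = rng.uniform(behaviour.carb_error_low, behaviour.carb_error_high)
                ann_g = grams * (1.0 + err)
                delay = rng.uniform(behaviour.delay_low, behaviour.delay_high) if delayed else 0.0
                ann_t = int(round(onset + delay))
            events.append(MealEvent(onset_min=onset, true_grams=float(grams),
                                    announced_grams=ann_g, announcement_min=ann_t,
                                    slot=slot))
    return events


# ---------------------------------------------------------------------------
# CGM noise
# ---------------------------------------------------------------------------

def cgm_noise(true: np.ndarray, sd: float, ar_coeff: float, seed: int) -> np.ndarray:
    """Add AR(1) sensor noise with stationary SD ``sd`` to a glucose series."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if not abs(ar_coeff) < 1:
        raise ValueError("|ar_coeff| must be < 1")
    true = np.asarray(true, dtype=float)
    if sd == 0:
        return true.copy()
    rng = np.random.default_rng(seed)
    innov_sd = sd * np.sqrt(1.0 - ar_coeff ** 2)
    eps = rng.normal(0.0, innov_sd, len(true))
    noise = np.empty(len(true))
    prev = rng.normal(0.0, sd)  # start in the stationary distribution
    for i in range(len(true)):
        prev = ar_coeff * prev + eps[i]
        noise[i] = prev
    return true + noise


class _Ar1Stream:
    """Incremental AR(1) noise generator for step-by-step simulation."""

    def __init__(self, sd: float, ar: float, rng: np.random.Generator) -> None:
        self.sd, self.ar = sd, ar
        self.rng = rng
        self.innov_sd = sd * np.sqrt(1.0 - ar ** 2) if sd > 0 else 0.0
        self.prev = rng.normal(0.0, sd) if sd > 0 else 0.0

    def __next__(self) -> float:
        if self.sd == 0:
            return 0.0
        self.prev = self.ar * self.prev + self.rng.normal(0.0, self.innov_sd)
        return self.prev


# ---------------------------------------------------------------------------
# physiology engine
# ---------------------------------------------------------------------------

class SimulationError(RuntimeError):
    pass


class SubjectSimulator:
    """Stepwise glucose-insulin simulator for one subject.

    State variables: plasma glucose G (mg/dL); remote insulin action X
    (mg/dL/min); SC insulin depot S1, S2 (U); gut carbohydrate Q1, Q2 (g).

        dS1/dt = u(t) - S1/ti            dQ1/dt = D(t) - Q1/tm
        dS2/dt = (S1 - S2)/ti            dQ2/dt = (Q1 - Q2)/tm
        dX/dt  = (SI(t)*m_day*S2/ti - X)/tx
        dG/dt  = -SG*(G - Gb) - X*G/Gb + kc*Q2/tm

    where SI(t) is the sinusoidal insulin sensitivity, m_day the per-day
    absorption multiplier ~ U[1-v, 1+v], kc the per-gram glucose rise, and the
    X*G/Gb term scales insulin action down at low glucose.  Integrated with a
    1-min Euler step, sampled every 5 min; the CGM adds AR(1) noise.
    """

    def __init__(self, params: SubjectParams, events: Sequence[MealEvent],
                 days: int, seed: int, cgm_noise_sd: float = 7.0,
                 cgm_noise_ar: float = 0.7) -> None:
        if days < 1:
            raise ValueError("days must be >= 1")
        horizon = days * 24 * 60
        for ev in events:
            if not 0 <= ev.onset_min < horizon:
                raise ValueError("meal events must fall within the simulated horizon")
        self.params = params
        self.days = days
        self.n_steps = days * STEPS_PER_DAY
        rng = np.random.default_rng(seed)
        self._noise = _Ar1Stream(cgm_noise_sd, cgm_noise_ar, rng)
        v = params.insulin_absorption_var
        self._day_mult = rng.uniform(1.0 - v, 1.0 + v, days) if v > 0 else np.ones(days)
        # grams entering the gut at each internal minute
        self._meal_grams = np.zeros(int(horizon / _ODE_DT))
        for ev in events:
            self._meal_grams[int(ev.onset_min / _ODE_DT)] += ev.true_grams

        # start at fasting equilibrium under the nominal basal
        ub = params.basal_rate
        self.G = params.fasting_glucose(ub)
        self.X = params.insulin_sensitivity_base * ub / 60.0
        depot = ub / 60.0 * params.insulin_action_time  # S/ti = u at steady state
        self.S1 = self.S2 = depot
        self.Q1 = self.Q2 = 0.0
        self.t_min = 0.0
        self.step_index = 0

    def step(self, basal_uhr: float, bolus_u: float) -> tuple[float, float]:
        """Advance 5 minutes under the commanded insulin; return (CGM, true G)."""
        if basal_uhr < 0 or bolus_u < 0:
            raise ValueError("insulin delivery cannot be negative")
        p = self.params
        ti, tm, tx = p.insulin_action_time, p.carb_absorption_time, p.remote_action_time
        sg, gb, kc = p.glucose_effectiveness, p.body_glucose_setpoint, p.carb_gain
        n_sub = int(STEP_MIN / _ODE_DT)
        self.S1 += bolus_u  # bolus enters the depot at the start of the step
        for k in range(n_sub):
            day = min(int(self.t_min // (24 * 60)), self.days - 1)
            si = p.insulin_sensitivity_at(self.t_min) * self._day_mult[day]
            idx = int(self.t_min / _ODE_DT)
            if idx < len(self._meal_grams):
                self.Q1 += self._meal_grams[idx]
            u = basal_uhr / 60.0  # U/min
            dS1 = u - self.S1 / ti
            dS2 = (self.S1 - self.S2) / ti
            dQ1 = -self.Q1 / tm
            dQ2 = (self.Q1 - self.Q2) / tm
            dX = (si * self.S2 / ti - self.X) / tx
            dG = -sg * (self.G - gb) - self.X * self.G / gb + kc * self.Q2 / tm
            self.S1 += _ODE_DT * dS1
            self.S2 += _ODE_DT * dS2
            self.Q1 += _ODE_DT * dQ1
            self.Q2 += _ODE_DT * dQ2
            self.X += _ODE_DT * dX
            self.G += _ODE_DT * dG
            self.t_min += _ODE_DT
            if not np.isfinite(self.G) or self.G <= 0:
                raise SimulationError(
                    f"glucose left the physiological range at t={self.t_min:.0f} min "
                    f"(step {self.step_index}): G={self.G!r}")
        self.step_index += 1
        cgm = self.G + next(self._noise)
        cgm = max(cgm, 1.0)  # CGM floor; keeps the timeline positive
        return float(cgm), float(self.G)


DosingCallback = Callable[[int, float], tuple[float, float]]


def simulate_subject(params: SubjectParams, events: Sequence[MealEvent],
                     dosing: DosingCallback, days: int, seed: int,
                     cgm_noise_sd: float = 7.0, cgm_noise_ar: float = 0.7,
                     ) -> GlucoseTimeline:
    """Open-loop simulation driver.

    ``dosing(step_index, last_cgm) -> (basal U/h, bolus U)`` is consulted once
    per 5-min step; ``last_cgm`` is the most recent CGM sample (the fasting
    equilibrium before the first step).
    """
    sim = SubjectSimulator(params, events, days, seed, cgm_noise_sd, cgm_noise_ar)
    n = sim.n_steps
    glucose = np.empty(n)
    true_g = np.empty(n)
    basal = np.empty(n)
    bolus = np.empty(n)
    carbs = np.zeros(n)
    announced = np.zeros(n)
    for ev in events:
        carbs[ev.onset_min // STEP_MIN] += ev.true_grams
        if ev.announced:
            announced[min(ev.announcement_min // STEP_MIN, n - 1)] += ev.announced_grams
    last_cgm = sim.G
    for i in range(n):
        b, u = dosing(i, last_cgm)
        glucose[i], true_g[i] = sim.step(b, u)
        basal[i], bolus[i] = b, u
        last_cgm = glucose[i]
    return GlucoseTimeline(glucose=glucose, true_glucose=true_g, basal=basal,
                           bolus=bolus, carbs=carbs, announced_carbs=announced)


def constant_basal(rate_uhr: float) -> DosingCallback:
    """Dosing callback delivering a fixed basal and no boluses."""
    return lambda step, cgm: (rate_uhr, 0.0)
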