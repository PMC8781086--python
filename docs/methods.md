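# Methods

## Overview

`mealsense` implements a fully automated meal-handling layer for closed-loop
insulin delivery ("artificial pancreas") systems.  Its core is a multitask
quantile forecaster: a sequence-to-sequence LSTM that predicts the most recent
20 minutes of the glucose trajectory at the 2.5th, 50th and 97.5th
conditional quantiles, trained with the pinball loss.  The 95% prediction
interval captures the aleatoric noise in CGM readings, insulin records and
announced meals; a *persistent* excursion of the CGM above the upper quantile
is therefore evidence of a missing input — an unannounced meal.  Detection
triggers an inverse-input search that finds the smallest carbohydrate amount
which, fed back into the model, reconciles the median forecast with the
observed CGM; that estimate drives a conservatively weighted meal bolus.

## Forecaster

**Inputs.** Encoder: per 5-min step, (CGM glucose mg/dL, insulin delivered U,
announced carbohydrate g) over a 2-h history (24 steps; the history length is
configurable — 2 h spans the bulk of meal absorption while keeping training
desk-scale).  Decoder: the exogenous (insulin, carbs) of the final 4 steps.
The decoder never sees the last 20 min of CGM, so the model *reconstructs*
the present from context; detection compares that reconstruction with what
the sensor actually reports.

**Architecture.** Encoder and decoder LSTMs of 64 cells; the decoder is
initialised with the final encoder state; one shared linear layer maps each
decoder hidden state to the three quantile outputs.  No crossing constraint
is imposed across heads; the crossing rate is measured instead and is ~0 on
the surrogate data.  The network is implemented directly in numpy
(`_qlstm.py`) with hand-derived backpropagation through time — the model is
small enough that a framework adds nothing but a dependency.

**Loss.** Pinball loss per head, implemented in the standard non-negative
form: tau·(y−ŷ) for under-prediction, (1−tau)·(ŷ−y) for over-prediction.
At tau = 0.5 this is half the absolute error, which keeps the median head an
MAE regressor.  The three head losses are averaged uniformly.

**Training protocol.** Two stages: a population model on pooled subject data
(Adam, lr 1e-3), then per-subject fine-tuning (lr 1e-4).  Batch size 128, at
most 100 epochs, early stopping on validation total loss with patience 20
and minimum improvement 1e-4, best weights restored.  Splits are
chronological (last 20% validation) to avoid look-ahead leakage.  Per-feature
min-max normalisation is computed on the population training split and frozen
into the model bundle; fine-tuning and inference reuse it unchanged.
Gradient clipping at global norm 1.0 guards rare unstable batches.  Training
maths run in float32; parameter updates are deterministic given the seed.

## Detection rule

At each sample the CGM is compared with the upper quantile at the final
decoder step (the only step aligned with "now").  A counter k increments
while CGM > upper bound and resets to zero otherwise.  A flag requires

* k > N with N = 2 — i.e. three consecutive exceeding samples, 15 min;
* glucose rising at ≥ 1 mg/dL/min, measured as the least-squares slope of
  the last 3 CGM samples (10 min) — least squares damps single-sample noise;
* no accepted estimate within the preceding 60 min (refractory period,
  matched to the basal-suspension horizon, to avoid double-dosing one meal).
  Re-estimation after the refractory window is permitted if the exceedance
  persists, each estimate independently capped at 90 g.

## Carbohydrate estimation

With a flag active, candidate grams are injected into the encoder's
carbohydrate channel at the final encoder step — 20 min before the flag,
the onset implied by the persistence rule — and the model is re-run.  The
error criterion is the absolute difference between the median forecast and
the CGM at the present sample; the threshold epsilon is the fine-tuned
model's validation MAE (median head, final decoder step).  Search: 10 g
coarse increments until the error drops below epsilon, then a 1 g walk
restarted from one coarse step back; the first candidate meeting the
threshold is returned.  Estimates cap at 90 g to bound overdosing.  If a
coarse increment fails to reduce the error, additional carbohydrate is not
moving the forecast toward the observation, the deviation is deemed
non-physiological, and the meal is discarded.  The dynamics check runs after
every coarse increment (only while the error still exceeds epsilon), so a
non-responding model is rejected after two model calls.

## Closed-loop harness

Three configurations share one feedback layer — a clamped
proportional-derivative basal modulation around a 120 mg/dL target
(kp = 0.015 U/h per mg/dL, kd = 0.5 U/h per mg/dL/min, clamp 0–3x nominal
basal).  The detection/estimation algorithm is controller-agnostic; this
simple layer stands in for any production controller.

* **nma** — feedback only; fully closed loop, no meal information.
* **md** — nma plus automatic boluses: an accepted estimate delivers
  W·grams/ICR with W = 0.5 at the next step, suspends basal for exactly
  12 steps (1 h), and writes the estimate into the announced-carbohydrate
  channel at the inferred onset so later forecasts explain the excursion.
  No correction bolus accompanies a meal bolus.
* **ma** — hybrid loop: behaviour-model announcements (with skips, delays
  and counting error) bolus announced/ICR at announcement time (W = 1,
  a user pre-bolusing deliberately, not the cautious automatic path).

## Surrogate simulator

No public dataset exists for this protocol, so the package ships a surrogate
type 1 diabetes simulator.  Physiology: Bergman-style minimal model with a
two-compartment gut cascade (rate-of-appearance peak at 40 min) and a
two-compartment subcutaneous insulin depot (peak at 55 min), remote insulin
action with a 40-min lag, integrated by 1-min Euler steps and sampled every
5 min.  Insulin action scales with G/G_setpoint, which attenuates insulin
effect at low glucose.  Per-gram glucose rise is tied to the subject's
insulin sensitivity through the carb ratio, so that one unit covers exactly
`carb_ratio` grams — keeping the bolus arithmetic self-consistent.

Scenario statistics emulated: four daily meals of mean 70/100/30/80 g at
07:00/13:00/17:00/20:00, onset SD 60 min (days resampled if sampling would
reorder meals), size CV 10%; sinusoidal insulin-sensitivity variability
(default amplitude 30%, period 24 h, per-subject random phase); per-day
insulin-absorption multiplier uniform on ±30%; carb-counting error uniform
on [−30%, +10%]; on average 2.5 announcements skipped and 2 delayed per week
(Bernoulli per event, delays uniform on 15–60 min).  CGM noise is AR(1) with
stationary SD 7 mg/dL and coefficient 0.7 — the standard shape of CGM error
models.  The 17:00 30 g event is the snack slot for meals-only metrics.

What the surrogate does **not** model: meal-composition effects (fat/protein,
variable absorption profiles), exercise, illness, sensor dropouts or drift,
pump quantisation, and the circadian structure of real insulin needs beyond
one sinusoid.  Passing benchmarks on it therefore demonstrates the internal
consistency of the detection/estimation machinery under realistic noise and
behaviour statistics, not clinical performance.

## Evaluation

Detections match meals greedily in time order: each flag claims the most
recent unmatched meal within 120 min before it; unmatched flags are false
positives, unmatched meals false negatives.  On random instances this greedy
matching attains the brute-force maximum number of true positives (the
windows are equal length; verified by test).  Precision and recall are
percentages; F is the harmonic mean as a fraction.  Delays are summarised by
the median (primary) with mean ± SD alongside.  For meals-only metrics a
detection matched to a snack is excluded rather than charged as a false
positive.

Glycaemic metrics: TIR (70 < BG < 180), TAR (BG ≥ 180), TBR (BG ≤ 70) —
boundaries follow the printed inequalities; Kovatchev risk indices with the
standard constants f(BG) = 1.509((ln BG)^1.084 − 5.381), risk 10f²,
LBGI/HBGI the negative/positive means, RI their sum.  CVGA classifies each
subject's (min BG, max BG) over the assessment period on the standard grid
(boundaries 90/70 on minima, 180/300 on maxima), with the zone layout chosen
so that the ordering A < B < C < D < E is monotone in both axes.  Paired
comparisons use Shapiro–Wilk at 0.05 on the differences to select a paired
t-test or Wilcoxon signed-rank, with Bonferroni-adjusted thresholds.

## Benchmark problem sizes

The packaged benchmarks are desk-scale by design: the calibration benchmark
trains on one subject × 3 weeks and evaluates coverage on the final ~20% of
windows; the cohort benchmark uses 3 subjects × 2 training weeks (pooled for
the population stage) and 3 held-out test weeks per subject.  Cohort
heterogeneity: insulin sensitivity ~ N(40, 4) mg/dL/U, carb ratio
~ N(10, 1) g/U, random sinusoid phase, basal set analytically to hold
fasting glucose at 115 mg/dL.  All benchmark quantities are computed at run
time from these pipelines; none are stored.

## Known limitations

* The estimator inherits the forecaster's local biases: epsilon is a global
  validation MAE, so locally miscalibrated regions under- or over-estimate.
* A single injected onset (20 min before the flag) misplaces slow meals;
  the refractory re-estimation path partially compensates.
* The PD feedback layer is deliberately generic; absolute glycaemic numbers
  depend on it and on the surrogate physiology, so only directional
  comparisons between modes are meaningful.
* Quantile heads are trained jointly but unconstrained; crossing is possible
  in principle, though not observed at measurable rates on surrogate data.
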