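"""End-to-end study workflows.

These functions tie the modules together into the benchmark pipelines used by
the test suite, the acceptance script and the CLI: cohort generation,
two-stage training, forecaster calibration, and the closed-loop detection /
control comparison.  All randomness derives from a single integer seed via
``numpy.random.SeedSequence`` spawning, so every pipeline is reproducible.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .control_harness import ControllerConfig, LoopRecord, run_closed_loop
from .detector import DetectorConfig
from .evaluation import (MatchResult, detection_report, fscore,
                         glycaemic_summary, precision, recall, delay_summary)
from .forecaster import (ModelBundle, TrainingConfig, build_windows,
                         finetune_individual, interval_coverage,
                         train_population)
from .scenario_sim import (BehaviourParams, GlucoseTimeline, MealProtocol,
                           SubjectParams, SubjectScenario, sample_scenario)


def _ints(ss: np.random.SeedSequence, n: int) -> list[int]:
    """Derive n independent integer seeds (< 2**31) from a seed sequence."""
    return [int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
            for child in ss.spawn(n)]


def make_subject(seed: int, fasting_target: float = 115.0) -> SubjectParams:
    """Sample one virtual adult with modest parameter heterogeneity.

    Insulin sensitivity and carb ratio vary with ~10% CV around the adult
    defaults; the insulin-sensitivity sinusoid gets a random phase.  The
    nominal basal rate is set to hold fasting glucose at ``fasting_target``.
    """
    rng = np.random.default_rng(seed)
    si = float(np.clip(rng.normal(40.0, 4.0), 25.0, 60.0))
    icr = float(np.clip(rng.normal(10.0, 1.0), 6.0, 15.0))
    phase = float(rng.uniform(0.0, 24.0))
    base = SubjectParams(insulin_sensitivity_base=si, carb_ratio=icr,
                         si_sin_phase=phase)
    return replace(base, basal_rate=base.equilibrium_basal(fasting_target))


def make_scenario(params: SubjectParams, days: int, seed: int,
                  protocol: MealProtocol | None = None,
                  behaviour: BehaviourParams | None = None,
                  cgm_noise_sd: float = 7.0, cgm_noise_ar: float = 0.7,
                  ) -> SubjectScenario:
    protocol = protocol or MealProtocol()
    behaviour = behaviour or BehaviourParams()
    event_seed, sim_seed = _ints(np.random.SeedSequence(seed), 2)
    events = sample_scenario(protocol, behaviour, days, event_seed)
    return SubjectScenario(params=params, events=events, days=days,
                           seed=sim_seed, cgm_noise_sd=cgm_noise_sd,
                           cgm_noise_ar=cgm_noise_ar)


def training_timeline(scenario: SubjectScenario,
                      controller: ControllerConfig | None = None,
                      ) -> GlucoseTimeline:
    """Generate model-training data: the hybrid (announcement-driven) loop.

    Training data carries the behaviour model's announced meals in the
    carbohydrate channel, mirroring the offline data-collection setting in
    which a hybrid closed loop logs CGM, insulin and announcements.
    """
    controller = controller or ControllerConfig(mode="ma")
    if controller.mode != "ma":
        controller = replace(controller, mode="ma")
    timeline, _ = run_closed_loop(scenario, None, DetectorConfig(), controller)
    return timeline


# ---------------------------------------------------------------------------
# forecaster calibration (single subject)
# ---------------------------------------------------------------------------

def coverage_benchmark(seed: int, days: int = 21,
                       config: TrainingConfig | None = None) -> dict:
    """Train on one surrogate subject and measure held-out PI coverage.

    Returns the empirical coverage (%) of the (0.025, 0.975) interval at the
    final decoder step on the subject's chronological validation split, plus
    the quantile-crossing rate and validation MAE.
    """
    ss = np.random.SeedSequence(seed)
    subj_seed, scen_seed, train_seed = _ints(ss, 3)
    params = make_subject(subj_seed)
    scenario = make_scenario(params, days, scen_seed)
    timeline = training_timeline(scenario)
    config = config or TrainingConfig()
    config = replace(config, seed=train_seed)
    bundle = train_population([timeline], config)
    windows = build_windows(timeline, config.enc_len, stats=bundle.stats)
    n_train = int(np.floor(config.split * len(windows)))
    val = windows.subset(slice(n_train, len(windows)))
    out = interval_coverage(bundle, val)
    out["validation_mae"] = bundle.validation_mae
    return out


# ---------------------------------------------------------------------------
# cohort detection benchmark / closed-loop comparison
# ---------------------------------------------------------------------------

def cohort_benchmark(seed: int, n_subjects: int = 3, train_days: int = 14,
                     test_days: int = 21, config: TrainingConfig | None = None,
                     finetune_config: TrainingConfig | None = None,
                     detector: DetectorConfig | None = None,
                     controller: ControllerConfig | None = None,
                     modes: tuple[str, ...] = ("md", "nma"),
                     protocol: MealProtocol | None = None,
                     behaviour: BehaviourParams | None = None) -> dict:
    """Train the two-stage model on a cohort and run held-out closed loops.

    Per subject: a training scenario (hybrid loop with announcements) feeds
    the population model and per-subject fine-tuning; a fresh scenario of
    ``test_days`` is then run closed-loop in each requested mode with the
    fine-tuned model.  Detections are pooled across subjects for the
    precision/recall/F-score report (120-min matching), and per-subject
    glycaemic summaries are collected per mode.
    """
    protocol = protocol or MealProtocol()
    behaviour = behaviour or BehaviourParams()
    config = config or TrainingConfig()
    detector = detector or DetectorConfig()
    controller = controller or ControllerConfig()
    k_subj, k_train, k_test, k_fit = np.random.SeedSequence(seed).spawn(4)
    subj_seeds = _ints(k_subj, n_subjects)
    train_seeds = _ints(k_train, n_subjects)
    test_seeds = _ints(k_test, n_subjects)
    fit_seed = _ints(k_fit, 1)[0]

    subjects = [make_subject(s) for s in subj_seeds]
    train_scen = [make_scenario(p, train_days, s, protocol, behaviour)
                  for p, s in zip(subjects, train_seeds)]
    train_tl = [training_timeline(sc) for sc in train_scen]

    config = replace(config, seed=fit_seed)
    population = train_population(train_tl, config)
    finetune_config = finetune_config or config
    bundles = [finetune_individual(population, tl, finetune_config)
               for tl in train_tl]

    test_scen = [make_scenario(p, test_days, s, protocol, behaviour)
                 for p, s in zip(subjects, test_seeds)]

    runs: dict[str, list[tuple[GlucoseTimeline, LoopRecord]]] = {}
    for mode in modes:
        cconf = replace(controller, mode=mode)
        runs[mode] = [run_closed_loop(sc, b if mode == "md" else None,
                                      detector, cconf)
                      for sc, b in zip(test_scen, bundles)]

    out: dict = {"subjects": subjects, "bundles": bundles,
                 "test_scenarios": test_scen, "runs": runs,
                 "glycaemic": {}}
    for mode in modes:
        out["glycaemic"][mode] = [glycaemic_summary(tl.true_glucose)
                                  for tl, _ in runs[mode]]
    if "md" in modes:
        pooled = MatchResult(0, 0, 0)
        pooled_all = MatchResult(0, 0, 0)
        for sc, (tl, rec) in zip(test_scen, runs["md"]):
            rep = detection_report(sc.events, rec.detections,
                                   snack_slots=protocol.snack_slots)
            pooled = pooled + rep["meals"]
            pooled_all = pooled_all + rep["overall"]
        out["detection"] = {
            "meals": {"match": pooled, "precision": precision(pooled),
                      "recall": recall(pooled), "fscore": fscore(pooled),
                      "delay": delay_summary(pooled)},
            "overall": {"match": pooled_all, "precision": precision(pooled_all),
                        "recall": recall(pooled_all), "fscore": fscore(pooled_all),
                        "delay": delay_summary(pooled_all)},
        }
    return out
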