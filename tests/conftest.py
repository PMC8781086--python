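"""Shared fixtures: small trained models and scenarios, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from mealsense.control_harness import ControllerConfig, run_closed_loop
from mealsense.detector import DetectorConfig
from mealsense.forecaster import TrainingConfig, train_population
from mealsense.pipelines import make_scenario, make_subject, training_timeline
from mealsense.scenario_sim import BehaviourParams, SubjectParams


@pytest.fixture(scope="session")
def subject_params() -> SubjectParams:
    return SubjectParams()


@pytest.fixture(scope="session")
def quiet_params() -> SubjectParams:
    """Subject with all intra-day variability switched off."""
    return SubjectParams(si_sin_amplitude=0.0, insulin_absorption_var=0.0)


@pytest.fixture(scope="session")
def small_config() -> TrainingConfig:
    """Reduced training budget for unit-level model tests."""
    return TrainingConfig(lstm_cells=32, max_epochs=12, patience=4, seed=7)


@pytest.fixture(scope="session")
def tiny_bundle(small_config):
    """A real (small) model trained on one week of one surrogate subject."""
    params = make_subject(101)
    scenario = make_scenario(params, days=7, seed=202)
    timeline = training_timeline(scenario)
    bundle = train_population([timeline], small_config)
    return {"bundle": bundle, "params": params, "timeline": timeline}


@pytest.fixture(scope="session")
def md_run(tiny_bundle):
    """A short closed-loop run in meal-detection mode with the tiny model."""
    scenario = make_scenario(tiny_bundle["params"], days=3, seed=303,
                             behaviour=BehaviourParams(skip_rate=28.0 * 3,
                                                       delay_rate=0.0))
    # skip_rate set so every announcement is skipped: all meals unannounced
    timeline, record = run_closed_loop(scenario, tiny_bundle["bundle"],
                                       DetectorConfig(), ControllerConfig(mode="md"))
    return {"scenario": scenario, "timeline": timeline, "record": record}
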