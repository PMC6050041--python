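"""Shared fixtures: session-scoped synthetic populations run through the
full pipeline, reused by the unit, property, and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import scmotion as sm

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def meta_frame(cells: list[sm.CellGroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": np.arange(len(cells)),
            "cell_class": [c.cell_class for c in cells],
            "depth_um": [c.depth_um for c in cells],
            "fov_id": [c.fov_id for c in cells],
        }
    )


@pytest.fixture(scope="session")
def protocol81() -> sm.StimulusProtocol:
    return sm.build_direction_contrast_protocol(8, 4, seed=0)


@pytest.fixture(scope="session")
def recovery_run(protocol81):
    """320 excitatory center-responsive cells, default noise, through the
    trace pipeline; used for population-slope parameter recovery."""
    cfg = sm.excitatory_recovery_config()
    cells = sm.sample_population(cfg, 320, seed=11)
    rec = sm.simulate_recording(protocol81, cells, seed=12)
    result = sm.analyze_recording(rec, n_boot=2000, seed=13)
    return {"cells": cells, "result": result, "protocol": protocol81}


@pytest.fixture(scope="session")
def mixed_run(protocol81):
    """500-cell default mixed population (excitatory + inhibitory, superficial)
    analyzed from the trial-level generator path."""
    cells = sm.sample_population(sm.GeneratorConfig(), 500, seed=41)
    trials = sm.simulate_trial_table(protocol81, cells, seed=42)
    result = sm.analyze_trials(trials, protocol81, cell_meta=meta_frame(cells), n_boot=2000, seed=43)
    return {"cells": cells, "result": result, "protocol": protocol81}


@pytest.fixture(scope="session")
def depth_run(protocol81):
    """500-cell depth-survey population (10-205 um, depth gradients on)."""
    cells = sm.sample_population(sm.depth_survey_config(), 500, seed=31)
    trials = sm.simulate_trial_table(protocol81, cells, seed=32)
    result = sm.analyze_trials(trials, protocol81, cell_meta=meta_frame(cells), n_boot=2000, seed=33)
    return {"cells": cells, "result": result, "protocol": protocol81}


@pytest.fixture(scope="session")
def noiseless_run(protocol81):
    """Small noise-free excitatory population through the full trace pipeline,
    for generator -> pipeline round-trip checks."""
    cfg = sm.excitatory_recovery_config()
    cfg.noise_sd = 0.0
    cells = sm.sample_population(cfg, 12, seed=7)
    rec = sm.simulate_recording(protocol81, cells, seed=2)
    trials = sm.build_response_table(rec)
    return {"cells": cells, "recording": rec, "trials": trials, "protocol": protocol81}
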