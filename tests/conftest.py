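"""Shared fixtures: small synthetic recordings generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from scoper import synth
from scoper.io import RunConfig


@pytest.fixture(scope="session")
def clean_recording():
    """180-s zero-noise single-stage recording with ground truth."""
    script = synth.EventScript(duration=180.0, stage_plan=[(0.0, "light")])
    rec, track, truth = synth.generate_recording(
        script=script, seed=11, return_truth=True
    )
    return rec, track, truth


@pytest.fixture(scope="session")
def eventful_recording():
    """10-min noisy recording with stages, one apnea and one hypopnea."""
    script = synth.EventScript(
        duration=600.0,
        events=[(150.0, 25.0, "apnea", 1.0), (400.0, 20.0, "hypopnea", 0.6)],
        stage_plan=[(0.0, "wake"), (90.0, "light"), (300.0, "rem")],
    )
    rec, track, truth = synth.generate_recording(
        script=script,
        noise_sd={"ecg": 0.02, "acc_x": 0.003, "acc_y": 0.003, "acc_z": 0.003,
                  "ppg_red": 5.0, "ppg_ir": 5.0},
        seed=13,
        return_truth=True,
    )
    return rec, track, truth


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=0)
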