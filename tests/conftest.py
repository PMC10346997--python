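"""Shared fixtures: synthetic windows and records with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from hankelppg import SynthParams, generate
from tests_support import make_window

FS = 125.0


@pytest.fixture
def fs() -> float:
    return FS


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def clean_window():
    """8-s pre-filtered clean PPG window at 72 bpm."""
    ppg, _, _ = make_window()
    return ppg


@pytest.fixture
def walking_record():
    """20-s record at 80 bpm with a 2 Hz walking artifact at ratio 2."""
    params = SynthParams(duration_s=20.0, hr_profile=80.0,
                         motion_freq_hz=2.0, artifact_ratio=2.0, seed=42)
    return generate(params)
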