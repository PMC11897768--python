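"""Shared fixtures: one stimulus and a few small seeded populations.

Populations are session-scoped — generation dominates test runtime, and
every consumer treats them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

import chirpcode as cc
from chirpcode.synthetic import UnitGroundTruth, rate_model, sample_spikes


@pytest.fixture(scope="session")
def stim():
    return cc.build_chirp(1000.0, 16.97)


@pytest.fixture(scope="session")
def on_sustained_trials(stim):
    """High-gain sustained ON unit, perfectly reliable; 10 trials."""
    gt = UnitGroundTruth(
        polarity_weights=(1.0, 0.0),
        latency_s=0.043,
        transience_tau_s=np.inf,
        baseline_rate=2.0,
        gain=40.0,
    )
    return sample_spikes(rate_model(gt, stim), stim, 10, 1.0, seed=12345)


@pytest.fixture(scope="session")
def off_trials(stim):
    gt = UnitGroundTruth(
        polarity_weights=(0.0, 1.0),
        latency_s=0.03,
        transience_tau_s=0.4,
        baseline_rate=2.0,
        gain=40.0,
    )
    return sample_spikes(rate_model(gt, stim), stim, 10, 1.0, seed=54321)


@pytest.fixture(scope="session")
def small_grm6():
    return cc.make_population("grm6_like", 40, 10, seed=7)


@pytest.fixture(scope="session")
def small_brn3c():
    return cc.make_population("brn3c_like", 40, 10, seed=8)
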