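"""Shared fixtures: seeded trial logs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from herdlab import PolicyConfig, WorldConfig, run_trial

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def failed_trial_log():
    """A full-length failed trial at default settings (27,000 samples).

    Fog + compass + partitioned sweep reliably runs to the 300 s ceiling,
    giving the canonical full-duration log for I/O, series-length, and
    speed-cap checks.
    """
    world = WorldConfig()
    policy = PolicyConfig(
        strategy="partitioned_sweep", global_info=False, sense_radius=10.0
    )
    log, outcome = run_trial(world, [policy] * 3, seed=7)
    assert outcome == "fail"
    return log


@pytest.fixture(scope="session")
def short_trial_log():
    """A cheap 20 s trial with 3 targets for I/O and pipeline tests."""
    import dataclasses

    world = dataclasses.replace(WorldConfig(), trial_max=20.0, n_targets=3)
    policy = PolicyConfig(strategy="corral_nearest", global_info=True)
    log, _ = run_trial(world, [policy] * 3, seed=11)
    return log


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
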