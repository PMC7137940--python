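"""Shared fixtures: simulated trials reused across the suite.

All fixtures are seeded; the expensive full-trial simulations are
session-scoped so each is integrated and processed exactly once.
"""

from __future__ import annotations

import pytest

from cobia_resp.config import default_config
from cobia_resp.sim_trial import simulate_trial
from cobia_resp.summary_io import process_trial


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def trial24_noiseless(cfg):
    """Noise-free 24 deg C trial: the discretisation-only reference."""
    return simulate_trial(cfg, 24.0, seed=101, noise_sd=0.0)


@pytest.fixture(scope="session")
def out24_noiseless(cfg, trial24_noiseless):
    t = trial24_noiseless
    return process_trial(t.trace, t.events, t.fish, t.ctx, config=cfg)


@pytest.fixture(scope="session")
def trial24(cfg):
    """One 24 deg C trial at the default (calibrated) sensor noise."""
    return simulate_trial(cfg, 24.0, seed=202)


@pytest.fixture(scope="session")
def out24(cfg, trial24):
    t = trial24
    return process_trial(
        t.trace, t.events, t.fish, t.ctx, config=cfg, vent_raw=t.ventilation
    )


@pytest.fixture(scope="session")
def trial28(cfg):
    """28 deg C trial used by the ventilation analyses."""
    return simulate_trial(cfg, 28.0, seed=303)


@pytest.fixture(scope="session")
def out28(cfg, trial28):
    t = trial28
    return process_trial(
        t.trace, t.events, t.fish, t.ctx, config=cfg, vent_raw=t.ventilation
    )
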