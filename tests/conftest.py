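"""Shared fixtures: calibrated models and pre-run reference scenarios."""

import pytest

from gmpc.ratemap import DEFAULT_ANCHORS, RateMap, calibrate_toy_model
from gmpc.scenarios import run_scenario, shipped_scenarios


@pytest.fixture(scope="session")
def ratemap() -> RateMap:
    return RateMap.from_anchors(DEFAULT_ANCHORS)


@pytest.fixture(scope="session")
def toy():
    return calibrate_toy_model(DEFAULT_ANCHORS)


@pytest.fixture(scope="session")
def shipped_runs():
    """All packaged scenarios executed once (seed 1): id -> (scenario, traj, log, metrics)."""
    out = {}
    for sid, sc in shipped_scenarios(seed=1).items():
        traj, log, metrics = run_scenario(sc)
        out[sid] = (sc, traj, log, metrics)
    return out
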