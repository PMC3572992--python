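"""Shared fixtures: the expensive biophysical simulations are run once per
session and reused by the unit, property and acceptance tests."""

import numpy as np
import pytest

from clionesim.circuits import SRC_IDS, StimulusProtocol, build_full_model
from clionesim.engine import integrate
from clionesim import phaselock as pl

HUNTING_DURATION = 120000.0   # ms
ROUTINE_DURATION = 60000.0
I_STATOLITH = 3.0
I_HUNTING = 3.0
ENVELOPE_MS = 400.0


@pytest.fixture(scope="session")
def hunting_run():
    """120 s full-model hunting simulation (the shipped scenario, seed 0)."""
    net = build_full_model(hunting=True)
    proto = StimulusProtocol(duration=HUNTING_DURATION, hunting_on=True,
                             I_hunting=I_HUNTING, seed=0)
    return integrate(net, proto)


@pytest.fixture(scope="session")
def hunting_runs_pool(hunting_run):
    """Three 120 s hunting series (different seeds) for pooled statistics."""
    out = [hunting_run]
    for seed in (1, 2):
        net = build_full_model(hunting=True)
        proto = StimulusProtocol(duration=HUNTING_DURATION, hunting_on=True,
                                 I_hunting=I_HUNTING, seed=seed)
        out.append(integrate(net, proto))
    return out


@pytest.fixture(scope="session")
def hunting_seq(hunting_run):
    """Compressed activity-word sequence of the shipped hunting run."""
    V = np.vstack([hunting_run.trace(c) for c in SRC_IDS])
    return pl.compress(pl.discretize(V, hunting_run.t_grid, 0.0,
                                     envelope_ms=ENVELOPE_MS))


@pytest.fixture(scope="session")
def routine_run():
    """60 s routine simulation with a posture change (SRC1 -> SRC6 at 30 s)."""
    net = build_full_model(hunting=False)
    proto = StimulusProtocol(
        duration=ROUTINE_DURATION, pressed_src="SRC1", I_statolith=I_STATOLITH,
        switch_events=((30000.0, "SRC6"),), seed=0)
    return integrate(net, proto)


@pytest.fixture(scope="session")
def wta_runs():
    """27 s routine runs, one per pressed receptor (no switch)."""
    out = {}
    for pressed in SRC_IDS:
        net = build_full_model(hunting=False)
        proto = StimulusProtocol(duration=27000.0, pressed_src=pressed,
                                 I_statolith=I_STATOLITH, seed=3)
        out[pressed] = integrate(net, proto)
    return out
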