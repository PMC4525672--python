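"""Shared fixtures.

Expensive simulation runs are session-scoped and shared between the
unit and acceptance layers; everything is deterministic, so sharing is
safe.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

# property tests must behave identically on every machine and rerun
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mucodyn import (
    LungVolumes,
    build_pv_curves,
    build_tree_spec,
    run_simulation,
    scenario_preset,
)
from mucodyn.dynamics import find_rest_state
from mucodyn.fixtures import default_mucus_profile, zero_mucus_profile
from mucodyn.two_phase_flow import FluidConstants


@pytest.fixture(scope="session")
def tree():
    return build_tree_spec()


@pytest.fixture(scope="session")
def vols():
    return LungVolumes()


@pytest.fixture(scope="session")
def curves(vols):
    return build_pv_curves(vols)


@pytest.fixture(scope="session")
def fluids():
    return FluidConstants()


@pytest.fixture(scope="session")
def profile():
    return default_mucus_profile()


@pytest.fixture(scope="session")
def rest_state(curves, tree, profile):
    return find_rest_state(curves, tree, profile)


@pytest.fixture(scope="session")
def vent_run(tree, curves, profile):
    """25 s of quiet breathing on the default mucus distribution."""
    spec, _, cfg = scenario_preset("ventilation")
    return run_simulation(spec, profile, cfg, tree=tree, curves=curves,
                          duration=25.0, record_stride=5)


@pytest.fixture(scope="session")
def vent_run_clean(tree, curves):
    """25 s of quiet breathing on a mucus-free lung."""
    spec, _, cfg = scenario_preset("ventilation")
    return run_simulation(spec, zero_mucus_profile(), cfg, tree=tree,
                          curves=curves, duration=25.0, record_stride=5)


@pytest.fixture(scope="session")
def manual20_run(tree, curves, profile):
    """The full 230-s manual physiotherapy session at P_cp = 20 cmH2O."""
    spec, _, cfg = scenario_preset("manual_sweep", pcp_cmH2O=20.0)
    return run_simulation(spec, profile, cfg, tree=tree, curves=curves,
                          record_stride=20)


def manual_short_run(tree, curves, profile, pcp, duration=60.0):
    """A scaled-down manual session (10 s lead-in/tail, 40 s of pushes)."""
    spec, _, cfg = scenario_preset("manual_sweep", pcp_cmH2O=pcp,
                                   duration=duration)
    return run_simulation(spec, profile, cfg, tree=tree, curves=curves,
                          duration=duration, record_stride=20)


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: draws never depend on test order
    return np.random.default_rng(20230822)
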