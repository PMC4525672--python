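"""Outcome measures: resistance ratio, mean mucus position, Shrek, comfort."""

import numpy as np
import pytest

from mucodyn.dynamics import find_rest_state
from mucodyn.fixtures import MucusProfile, zero_mucus_profile
from mucodyn.metrics import (
    comfort,
    compliance_shrek,
    instantaneous_shrek,
    mean_mucus_position,
    relative_resistance,
    resistance_from_mucus,
    shrek,
    tree_resistance,
)
from mucodyn.two_phase_flow import FluidConstants


class TestRelativeResistance:
    def test_identity_is_one(self, rest_state, tree, curves):
        assert relative_resistance(rest_state, rest_state, tree, curves) == 1.0

    def test_removing_mucus_reduces_resistance(self, rest_state, tree, curves,
                                               fluids):
        clean = find_rest_state(curves, tree, zero_mucus_profile())
        assert relative_resistance(clean, rest_state, tree, curves) < 1.0

    def test_scale_invariant_in_air_viscosity(self, rest_state, tree, curves):
        a = relative_resistance(rest_state, rest_state, tree, curves,
                                FluidConstants())
        b = relative_resistance(rest_state, rest_state, tree, curves,
                                FluidConstants(mu_air=3.6e-5))
        assert a == pytest.approx(b)

    def test_fourth_power_law(self, tree, fluids):
        S = np.full(23, 1e-3) * tree.multiplicity
        R1 = tree_resistance(tree, S, fluids)
        R2 = tree_resistance(tree, S / 2.0, fluids)
        assert R2 == pytest.approx(4.0 * R1)  # area halved -> r^4 quartered


class TestMeanMucusPosition:
    def test_single_generation(self, curves, tree):
        fill = [0.0] * 17
        fill[8] = 0.3
        rest = find_rest_state(curves, tree, MucusProfile(tuple(fill), "g8"))
        assert mean_mucus_position(rest, tree) == pytest.approx(8.0, abs=1e-9)

    def test_expelled_volume_lowers_the_mean(self, rest_state, tree):
        shifted = rest_state.copy()
        shifted.v_out = 0.2 * float(rest_state.Vm.sum())
        assert mean_mucus_position(shifted, tree) < mean_mucus_position(
            rest_state, tree
        )

    def test_scale_invariance(self, curves, tree, rest_state):
        doubled = rest_state.copy()
        doubled.Vm = 2.0 * rest_state.Vm
        assert mean_mucus_position(doubled, tree) == pytest.approx(
            mean_mucus_position(rest_state, tree)
        )

    def test_undefined_without_mucus(self, curves, tree):
        clean = find_rest_state(curves, tree, zero_mucus_profile())
        with pytest.raises(ValueError):
            mean_mucus_position(clean, tree)


class TestShrek:
    def test_zero_flow(self, rest_state, tree, fluids):
        assert instantaneous_shrek(tree, np.zeros(23), rest_state.S_a,
                                   fluids) == 0.0

    def test_single_airway_normalization(self, tree, fluids):
        # one tube with 4 mu phi / (pi r^3) = sigma0 contributes 1/N
        r = 1e-3
        phi = fluids.sigma0 * np.pi * r**3 / (4 * fluids.mu_air)
        phis = np.zeros(23)
        phis[0] = phi
        S = np.full(23, np.pi * r**2) * tree.multiplicity
        assert instantaneous_shrek(tree, phis, S, fluids) == pytest.approx(
            1.0 / 17.0
        )

    def test_approximation_within_factor_two(self, vent_run):
        sh = shrek(vent_run)
        m = np.abs(vent_run.phi_mouth) > 0.2 * np.abs(vent_run.phi_mouth).max()
        ratio = sh["iSh_approx"][m] / sh["iSh"][m]
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)

    def test_compliance_diagnostic_positive(self, vent_run):
        est = compliance_shrek(vent_run)
        est = est[np.isfinite(est)]
        assert est.size > 0 and np.all(est >= 0)


class TestComfort:
    def test_ventilation_vs_itself_is_zero(self, vent_run):
        out = comfort(vent_run, vent_run)
        assert out["Com"] == 0.0
        assert np.all(out["iCom"] == 0.0)

    def test_nonnegative_trace(self, vent_run, vent_run_clean):
        out = comfort(vent_run, vent_run_clean)
        assert np.all(out["iCom"] >= 0.0)

    def test_mismatched_grids_rejected(self, vent_run, manual20_run):
        with pytest.raises(ValueError):
            comfort(manual20_run, vent_run)


def test_resistance_from_mucus_floor_guard(tree, rest_state, fluids):
    # a fully occluding load computes at the floor instead of diverging
    huge = rest_state.S_b[:17] * tree.lengths[:17] * 2.0
    R = resistance_from_mucus(tree, rest_state.S_b, huge, fluids)
    assert np.isfinite(R) and R > tree_resistance(tree, rest_state.S_b, fluids)
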