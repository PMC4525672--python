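"""Static mechanics: pressure-area law, PV curves, volume fixed point."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucodyn import lambert_area, solve_lung_volume, tracheobronchial_volume
from mucodyn.constitutive import (
    OutOfDomainError,
    alveolar_duct_unit,
    build_pv_curves,
    lambert_area_deriv_vec,
    lambert_area_vec,
    mechanics_map,
)
from mucodyn.units import from_cmH2O


class TestAirwayLaw:
    def test_zero_pressure_area_is_alpha0_Am(self, tree):
        g0 = tree.generations[0]
        # trachea: 0.882 * 2.37 cm^2
        assert lambert_area(g0, 0.0) * 1e4 == pytest.approx(2.0903, abs=2e-4)
        areas = lambert_area_vec(tree, np.zeros(17))
        assert np.allclose(areas, tree.alpha0 * tree.A_m, rtol=1e-12)

    def test_upper_asymptote_is_Am(self, tree):
        for g in tree.generations[:17]:
            assert lambert_area(g, 1e9) == pytest.approx(g.A_m, rel=1e-4)

    def test_high_precision_evaluation_gen16(self, tree):
        # independent arbitrary-precision evaluation of the printed formula
        from fractions import Fraction as F

        g = tree.generations[16]
        dP = F(500)
        alpha0, n2 = F("0.039"), 7
        alpha0p = F("24.3") / F(10**3)
        Am = F("180.00") / F(10**4)
        P2 = -n2 * (1 - alpha0) / alpha0p
        expected = (1 - (1 - alpha0) * (1 - dP / P2) ** (-n2)) * Am
        assert lambert_area(g, 500.0) == pytest.approx(float(expected),
                                                       rel=1e-6)

    def test_c1_continuity_at_zero_all_generations(self, tree):
        h = 1e-6
        up = lambert_area_vec(tree, np.full(17, h))
        dn = lambert_area_vec(tree, np.full(17, -h))
        val0 = tree.alpha0 * tree.A_m
        assert np.allclose(up, val0 + h * tree.alpha0_prime * tree.A_m,
                           rtol=1e-6)
        assert np.allclose(dn, val0 - h * tree.alpha0_prime * tree.A_m,
                           rtol=1e-6)
        d_up = lambert_area_deriv_vec(tree, np.full(17, h))
        d_dn = lambert_area_deriv_vec(tree, np.full(17, -h))
        assert np.allclose(d_up, d_dn, rtol=1e-4)

    def test_monotone_increasing(self, tree):
        grid = np.linspace(-3000, 3000, 801)[:, None]
        areas = lambert_area_vec(tree, np.broadcast_to(grid, (801, 17)))
        assert np.all(np.diff(areas, axis=0) >= 0)

    def test_acinar_generation_rejected(self, tree):
        with pytest.raises(ValueError):
            lambert_area(tree.generations[17], 0.0)

    def test_derivative_matches_finite_differences(self, tree, rng):
        dP = rng.uniform(-800, 800, size=(40, 17))
        h = 1e-4
        fd = (lambert_area_vec(tree, dP + h) - lambert_area_vec(tree, dP - h)) / (2 * h)
        an = lambert_area_deriv_vec(tree, dP)
        assert np.allclose(fd, an, rtol=1e-4, atol=1e-14)


class TestPVCurves:
    def test_frc_anchor(self, curves):
        assert curves.static_volume(0.0) == pytest.approx(3.25e-3, rel=1e-12)

    def test_rest_compliance_near_point_one_L_per_cmH2O(self, curves):
        c = (curves.static_volume(from_cmH2O(5)) -
             curves.static_volume(from_cmH2O(-5))) / 10.0
        assert c * 1e3 == pytest.approx(0.1, rel=0.08)

    def test_strictly_increasing(self, curves):
        grid = np.linspace(from_cmH2O(-30), from_cmH2O(30), 1000)
        assert np.all(np.diff(curves.static_volume(grid)) > 0)
        vgrid = np.linspace(1.6e-3, 6.4e-3, 1000)
        assert np.all(np.diff(curves.tissue_pressure(vgrid)) > 0)

    def test_inverse_round_trip(self, curves):
        dP = np.linspace(-2000, 2000, 41)
        back = curves.static_volume_inv(curves.static_volume(dP))
        assert np.allclose(back, dP, rtol=1e-9, atol=1e-6)

    def test_tissue_anchors(self, curves, vols):
        assert curves.tissue_pressure(vols.FRC) == pytest.approx(500.0)
        assert curves.tissue_pressure(vols.TLC) == pytest.approx(
            from_cmH2O(30), rel=1e-6
        )

    def test_tabulated_curves_and_validation(self, vols):
        p = np.linspace(-40, 40, 41)
        v = 1.5 + 5.0 / (1 + np.exp(-(p - 7.4) / 12.0))
        curves = build_pv_curves(vols, volume_table=np.column_stack([p, v]))
        mid = curves.static_volume(from_cmH2O(0.0))
        assert 1.5e-3 < mid < 6.5e-3
        bad = np.column_stack([p, v[::-1]])
        with pytest.raises(ValueError):
            build_pv_curves(vols, volume_table=bad)
        with pytest.raises(OutOfDomainError):
            curves.static_volume(from_cmH2O(200.0))


class TestLungVolume:
    def test_rest_equilibrium_volume(self, curves, tree):
        V = solve_lung_volume(curves, tree, np.zeros(23), 0.0)
        assert V == pytest.approx(3.25e-3, rel=1e-9)

    def test_residual_contract(self, curves, tree):
        from mucodyn.constitutive import _acinar_volume

        P = np.zeros(23)
        V = solve_lung_volume(curves, tree, P, 0.0)
        V_ac, _, _ = _acinar_volume(curves, tree, P, 0.0)
        resid = V - V_ac - tracheobronchial_volume(curves, tree, V, P)
        assert abs(resid) < 1e-9

    def test_negative_chest_pressure_inflates_by_tidal(self, curves, tree):
        V = solve_lung_volume(curves, tree, np.zeros(23), from_cmH2O(-5))
        assert V * 1e3 == pytest.approx(3.75, rel=0.01)

    def test_agrees_with_brute_force_scan(self, curves, tree, rng):
        from mucodyn.constitutive import _acinar_volume, lambert_area_vec

        grid = np.linspace(1.6e-3, 6.4e-3, 8_000)
        pt = curves.tissue_pressure(grid)[:, None]
        lengths = tree.lengths[:17]
        for _ in range(20):
            P = rng.uniform(-800, 800, size=23)
            P_ext = rng.uniform(-800, 800)
            V = solve_lung_volume(curves, tree, P, P_ext)
            V_ac, _, _ = _acinar_volume(curves, tree, P, P_ext)
            vtbt = lambert_area_vec(tree, pt - P[None, :17]) @ lengths
            resid = grid - V_ac - vtbt
            V_scan = grid[np.argmin(np.abs(resid))]
            assert abs(V - V_scan) < 2 * (grid[1] - grid[0])

    def test_out_of_domain_volume_rejected(self, curves, tree):
        with pytest.raises(OutOfDomainError):
            tracheobronchial_volume(curves, tree, 7e-3, np.zeros(23))


class TestAcinarUnits:
    def test_rest_alveolar_volume_and_duct_fraction(self, curves, tree):
        ac = alveolar_duct_unit(curves, tree, 0.0, 0.0)
        total_alv = 58 * ac.v_alv * tree.n_adu_total
        assert total_alv * 1e3 == pytest.approx(2.58, rel=0.1)
        duct = ac.duct_area * tree.generations[17].length
        assert duct / ac.v_adu == pytest.approx(0.17, rel=1e-12)

    def test_chest_pressure_shrinks_acini(self, curves, tree):
        lo = alveolar_duct_unit(curves, tree, 0.0, 200.0)
        hi = alveolar_duct_unit(curves, tree, 0.0, 0.0)
        assert lo.v_adu < hi.v_adu


class TestMechanicsMap:
    def test_rest_self_consistency(self, curves, tree):
        S_b, v_alv, V_L = mechanics_map(curves, tree, 0.0, np.zeros(23))
        assert V_L == pytest.approx(3.25e-3, rel=1e-9)
        vtbt = float(np.sum(S_b[:17] * tree.lengths[:17]))
        ducts = float(np.sum(S_b[17:] * tree.lengths[17:]))
        alv = float(np.sum(tree.multiplicity[17:] * 58 * v_alv))
        assert (vtbt + ducts + alv) == pytest.approx(V_L, rel=1e-6)
        # bronchial tree (conducting + duct lumens) near the printed 0.67 L
        assert (vtbt + ducts) * 1e3 == pytest.approx(0.67, rel=0.1)

    def test_chest_pressure_narrows_every_airway(self, curves, tree):
        open_, _, _ = mechanics_map(curves, tree, 0.0, np.zeros(23))
        squeezed, _, _ = mechanics_map(curves, tree, 500.0, np.zeros(23))
        assert np.all(squeezed < open_)

    @given(p=st.floats(-400, 400), pe=st.floats(-400, 400))
    @settings(max_examples=20, deadline=None)
    def test_continuity_in_pressures(self, curves, tree, p, pe):
        base, _, _ = mechanics_map(curves, tree, pe, np.full(23, p))
        near, _, _ = mechanics_map(curves, tree, pe + 1e-3,
                                   np.full(23, p + 1e-3))
        assert np.allclose(base, near, rtol=1e-4)
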