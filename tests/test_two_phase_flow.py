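"""Core-annular air/Bingham-mucus hydrodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucodyn.two_phase_flow import (
    AnnulusGeometry,
    FluidConstants,
    airway_air_resistance,
    flows_from_gradient,
    gradient_from_airflow,
    mucus_outflow,
    profile_oracle,
    yield_radius,
)

FL = FluidConstants()


def _random_case(rng):
    r_b = 10 ** rng.uniform(-4.2, -2)
    r_a = r_b * rng.uniform(0.05, 0.999)
    # span solid / partially yielded / fully yielded regimes
    C = rng.choice([-1.0, 1.0]) * (2 * FL.sigma0 / r_b) * 10 ** rng.uniform(-1, 3)
    return C, AnnulusGeometry(r_a, r_b)


def test_yield_radius():
    assert yield_radius(2.0, 0.1) == pytest.approx(0.1)
    assert yield_radius(-2000.0, 0.1) == pytest.approx(1e-4)
    assert yield_radius(0.0) == np.inf


def test_no_mucus_limit_is_poiseuille():
    g = AnnulusGeometry(1e-3, 1e-3)
    for C in (-2000.0, 500.0):
        f = flows_from_gradient(C, g)
        assert f["phi_air"] == pytest.approx(-C * np.pi * 1e-12 / (8 * FL.mu_air))
        assert f["phi_mucus"] == 0.0


def test_solid_annulus_air_core_poiseuille():
    g = AnnulusGeometry(0.5e-3, 1e-3)
    C = -100.0  # |C| < 2 sigma0 / r_b = 200: mucus solid
    f = flows_from_gradient(C, g)
    assert f["phi_mucus"] == 0.0
    assert f["phi_air"] == pytest.approx(
        -C * np.pi * (0.5e-3) ** 4 / (8 * FL.mu_air)
    )


def test_yield_dead_zone_exact(rng):
    for _ in range(50):
        r_b = 10 ** rng.uniform(-4, -2)
        r_a = r_b * rng.uniform(0.1, 0.95)
        C = rng.uniform(-1, 1) * 2 * FL.sigma0 / r_b  # |C| <= threshold
        assert mucus_outflow(C, AnnulusGeometry(r_a, r_b)) == 0.0


def test_antisymmetry(rng):
    for _ in range(50):
        C, g = _random_case(rng)
        fp = flows_from_gradient(C, g)
        fm = flows_from_gradient(-C, g)
        assert fp["phi_air"] == pytest.approx(-fm["phi_air"], rel=1e-12)
        assert fp["phi_mucus"] == pytest.approx(-fm["phi_mucus"], rel=1e-12)


def test_closed_forms_match_quadrature_oracle(rng):
    worst = 0.0
    for _ in range(1000):
        C, g = _random_case(rng)
        fc = flows_from_gradient(C, g)
        fo = profile_oracle(C, g)
        for k in ("phi_air", "phi_mucus"):
            if fc[k] == 0.0 and abs(fo[k]) < 1e-20:
                continue
            err = abs(fc[k] - fo[k]) / max(abs(fo[k]), abs(fc[k]))
            worst = max(worst, err)
    assert worst < 1e-7


def test_fluxes_monotone_nonincreasing_in_gradient(rng):
    for _ in range(20):
        r_b = 10 ** rng.uniform(-4, -2)
        g = AnnulusGeometry(r_b * rng.uniform(0.2, 0.95), r_b)
        Cs = np.linspace(-40 * FL.sigma0 / r_b, 40 * FL.sigma0 / r_b, 301)
        f = flows_from_gradient(Cs, fluids=FL, r_a=np.full_like(Cs, g.r_a),
                                r_b=np.full_like(Cs, g.r_b))
        assert np.all(np.diff(f["phi_air"]) <= 1e-18)
        assert np.all(np.diff(f["phi_mucus"]) <= 1e-18)


@given(
    log_rb=st.floats(-4.2, -2.0),
    frac=st.floats(0.05, 1.0),
    logc=st.floats(-2.0, 3.0),
    sign=st.sampled_from([-1.0, 1.0]),
)
@settings(max_examples=300, deadline=None)
def test_gradient_airflow_round_trip(log_rb, frac, logc, sign):
    r_b = 10.0**log_rb
    r_a = max(r_b * frac, 1e-7)
    C = sign * 2 * FL.sigma0 / r_b * 10.0**logc
    g = AnnulusGeometry(r_a, r_b)
    phi = flows_from_gradient(C, g)["phi_air"]
    back = gradient_from_airflow(phi, g)
    assert back == pytest.approx(C, rel=1e-8)


def test_zero_flow_zero_gradient():
    g = AnnulusGeometry(0.5e-3, 1e-3)
    assert gradient_from_airflow(0.0, g) == 0.0


def test_poiseuille_inversion_closed_form():
    g = AnnulusGeometry(1e-3, 1e-3)
    C = gradient_from_airflow(1e-6, g)  # 1 mL/s in a 1 mm tube
    assert C == pytest.approx(-8 * FL.mu_air * 1e-6 / (np.pi * 1e-12))
    assert C == pytest.approx(-45.84, rel=1e-3)


def test_infinite_mucus_viscosity_approaches_rigid_annulus():
    g = AnnulusGeometry(0.5e-3, 1e-3)
    C = -5000.0  # fully yielded at the default viscosity
    rigid = -C * np.pi * g.r_a**4 / (8 * FL.mu_air)
    last = np.inf
    for mu_m in (0.1, 1.0, 10.0, 1e3, 1e6):
        fl = FluidConstants(mu_mucus=mu_m)
        phi = flows_from_gradient(C, g, fl)["phi_air"]
        assert phi >= rigid * (1 - 1e-12)
        assert phi <= last + 1e-20
        last = phi
    assert last == pytest.approx(rigid, rel=1e-4)


def test_air_resistance_scaling():
    g = AnnulusGeometry(1e-3, 1e-3)
    R = airway_air_resistance(g, FL, length=0.01)
    assert R == pytest.approx(8 * FL.mu_air * 0.01 / (np.pi * 1e-12))
    g2 = AnnulusGeometry(0.5e-3, 1e-3)
    assert airway_air_resistance(g2, FL, length=0.01) == pytest.approx(16 * R)


def test_degenerate_geometry_rejected():
    with pytest.raises(ValueError):
        AnnulusGeometry(-1e-4, 1e-3)
    with pytest.raises(ValueError):
        AnnulusGeometry(2e-3, 1e-3)
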