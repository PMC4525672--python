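"""Core-annular flow of air inside a Bingham mucus layer.

A cylindrical airway of radius ``r_b`` carries a Newtonian air core of
radius ``r_a`` surrounded by a mucus annulus.  For fully developed
axisymmetric Stokes flow under an axial pressure gradient ``C`` (Pa/m),
the shear stress is ``tau(r) = C r / 2`` in both fluids.  The mucus is a
Bingham material with yield stress ``sigma0``: it is rigid wherever
``|tau| < sigma0``, i.e. inside the yield radius ``r0 = |2 sigma0 / C|``,
and flows with plastic viscosity ``mu_m`` outside it.  Three regimes
follow:

* ``r0 >= r_b``  -- the whole annulus is solid, anchored to the wall;
  the air core is plain Poiseuille flow with no slip at ``r_a``;
* ``r_a < r0 < r_b`` -- a sheared mucus layer against the wall carries a
  solid plug attached to the air interface;
* ``r0 <= r_a``  -- the annulus is fully yielded.

All fluxes integrate to piecewise polynomials in the radii, so both the
forward map (gradient -> fluxes) and its inverse (air flux -> gradient,
the network closure) are closed-form.  Sign convention: fluxes are
measured positive *down* the tree axis, so a flux has the sign of
``-C``; in the tree, mucus flux < 0 means motion toward the mouth.

A quadrature oracle (test-only) integrates the velocity profile
numerically for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MU_AIR = 1.8e-5  # Pa s
RHO_AIR = 1.0  # kg/m^3 (metadata; inertia neglected)
SIGMA0 = 0.1  # Pa, mucus yield stress
MU_MUCUS = 0.1  # Pa s, mucus plastic viscosity
RHO_MUCUS = 1000.0  # kg/m^3 (metadata)


@dataclass(frozen=True)
class FluidConstants:
    """Material constants of air and mucus."""

    mu_air: float = MU_AIR
    rho_air: float = RHO_AIR
    sigma0: float = SIGMA0
    mu_mucus: float = MU_MUCUS
    rho_mucus: float = RHO_MUCUS

    def __post_init__(self) -> None:
        for name in ("mu_air", "rho_air", "sigma0", "mu_mucus", "rho_mucus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class AnnulusGeometry:
    """Per-airway core and wall radii (m)."""

    r_a: float
    r_b: float

    def __post_init__(self) -> None:
        if self.r_a <= 0:
            raise ValueError("degenerate geometry: r_a <= 0")
        if self.r_a > self.r_b * (1.0 + 1e-12):
            raise ValueError("air core cannot exceed the bronchus radius")

    @classmethod
    def from_areas(cls, S_a: float, S_b: float, multiplicity: float = 1.0):
        """Radii from generation-summed areas and airway multiplicity."""
        return cls(
            r_a=float(np.sqrt(S_a / multiplicity / np.pi)),
            r_b=float(np.sqrt(S_b / multiplicity / np.pi)),
        )


def yield_radius(C: float, sigma0: float = SIGMA0) -> float:
    """Radius where the shear stress equals the yield stress: |2 sigma0/C|.

    Returns ``inf`` for a vanishing gradient (mucus solid everywhere).
    """
    if C == 0.0:
        return np.inf
    return abs(2.0 * sigma0 / C)


def _flux_magnitudes(C_hat, r_a, r_b, fluids: FluidConstants):
    """Unsigned (air, mucus) fluxes for |C| = C_hat, vectorized.

    ``a = clip(r0, r_a, r_b)`` is the inner edge of the sheared mucus
    zone; ``u_y`` the speed of the plug (and of the interface), and the
    sheared-zone flux integrates the classic Bingham profile.
    """
    C_hat = np.asarray(C_hat, dtype=float)
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    sig, mu_m, mu_a = fluids.sigma0, fluids.mu_mucus, fluids.mu_air
    with np.errstate(divide="ignore"):
        r0 = np.where(C_hat > 0, 2.0 * sig / np.where(C_hat > 0, C_hat, 1.0), np.inf)
    a = np.clip(r0, r_a, r_b)
    u_y = C_hat / (4.0 * mu_m) * (r_b**2 - a**2) - sig / mu_m * (r_b - a)
    u_y = np.maximum(u_y, 0.0)  # exact zero in the solid regime
    q_shear = C_hat * np.pi / (8.0 * mu_m) * (r_b**2 - a**2) ** 2 - (
        sig * np.pi / (3.0 * mu_m)
    ) * (r_b**3 - 3.0 * r_b * a**2 + 2.0 * a**3)
    q_shear = np.maximum(q_shear, 0.0)
    phi_m = u_y * np.pi * (a**2 - r_a**2) + q_shear
    phi_m = np.where(r0 >= r_b, 0.0, phi_m)  # exact yield dead-zone
    phi_a = u_y * np.pi * r_a**2 + C_hat * np.pi * r_a**4 / (8.0 * mu_a)
    return phi_a, phi_m


def flows_from_gradient(
    C: float | np.ndarray,
    geom: AnnulusGeometry | None = None,
    fluids: FluidConstants | None = None,
    *,
    r_a: np.ndarray | None = None,
    r_b: np.ndarray | None = None,
    rigid_interface: bool = False,
) -> dict:
    """Air and mucus fluxes (m^3/s) under pressure gradient ``C`` (Pa/m).

    Accepts either a single ``AnnulusGeometry`` or raw radius arrays for
    vectorized use.  With ``rigid_interface=True`` the interface
    velocity feedback on the air core is dropped (air sees a rigid
    annulus regardless of the mucus state); mucus flux is unchanged.
    """
    fluids = fluids or FluidConstants()
    if geom is not None:
        r_a, r_b = geom.r_a, geom.r_b
    C = np.asarray(C, dtype=float)
    s = np.sign(C)
    phi_a_hat, phi_m_hat = _flux_magnitudes(np.abs(C), r_a, r_b, fluids)
    if rigid_interface:
        phi_a_hat = np.abs(C) * np.pi * np.asarray(r_a, float) ** 4 / (8.0 * fluids.mu_air)
    phi_air = -s * phi_a_hat
    phi_mucus = -s * phi_m_hat
    if phi_air.ndim == 0:
        return {"phi_air": float(phi_air), "phi_mucus": float(phi_mucus)}
    return {"phi_air": phi_air, "phi_mucus": phi_mucus}


def mucus_outflow(
    C: float | np.ndarray,
    geom: AnnulusGeometry | None = None,
    fluids: FluidConstants | None = None,
    *,
    r_a: np.ndarray | None = None,
    r_b: np.ndarray | None = None,
) -> float | np.ndarray:
    """Mucus flux through the airway (negative = toward the mouth).

    Exactly zero on the yield dead-zone ``|C| <= 2 sigma0 / r_b``.
    """
    return flows_from_gradient(C, geom, fluids, r_a=r_a, r_b=r_b)["phi_mucus"]


def gradient_from_airflow(
    phi_air: float | np.ndarray,
    geom: AnnulusGeometry | None = None,
    fluids: FluidConstants | None = None,
    *,
    r_a: np.ndarray | None = None,
    r_b: np.ndarray | None = None,
    rigid_interface: bool = False,
) -> float | np.ndarray:
    """Invert the air-flux map: the pressure gradient driving ``phi_air``.

    The forward map is strictly monotone, piecewise closed-form in the
    three mucus regimes, so the inverse is exact:

    * rigid annulus: ``C = -8 mu_a phi / (pi r_a^4)`` (linear),
    * partially yielded: a quadratic in ``|C|`` (the plug speed is
      ``(|C| r_b - 2 sigma0)^2 / (4 mu_m |C|)``),
    * fully yielded: linear again (interface speed linear in ``|C|``).
    """
    fluids = fluids or FluidConstants()
    if geom is not None:
        r_a, r_b = geom.r_a, geom.r_b
    scalar = np.isscalar(phi_air) or np.ndim(phi_air) == 0
    phi = np.atleast_1d(np.asarray(phi_air, dtype=float))
    r_a = np.broadcast_to(np.asarray(r_a, dtype=float), phi.shape).astype(float)
    r_b = np.broadcast_to(np.asarray(r_b, dtype=float), phi.shape).astype(float)
    sig, mu_m, mu_a = fluids.sigma0, fluids.mu_mucus, fluids.mu_air

    s = -np.sign(phi)  # gradient has the sign opposite to the flux
    phi_hat = np.abs(phi)
    poise = np.pi * r_a**4 / (8.0 * mu_a)

    C1 = 2.0 * sig / r_b  # solid/partial boundary
    phi1 = C1 * poise
    # partial/liquid boundary, |C| = 2 sigma0 / r_a
    mucus = r_a < r_b * (1.0 - 1e-14)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi2 = np.where(
            mucus,
            np.pi * r_a * sig * (r_b - r_a) ** 2 / (2.0 * mu_m) + 2.0 * sig / r_a * poise,
            np.inf,
        )

    C_hat = phi_hat / poise  # rigid-annulus branch (also the no-mucus case)

    if rigid_interface:
        return float(s * C_hat) if scalar else (s * C_hat).reshape(np.shape(phi_air))

    partial = mucus & (phi_hat > phi1) & (phi_hat <= phi2)
    if np.any(partial):
        ra, rb, ph = r_a[partial], r_b[partial], phi_hat[partial]
        A = np.pi * ra**2 * rb**2 / (4.0 * mu_m) + np.pi * ra**4 / (8.0 * mu_a)
        B = -(np.pi * ra**2 * rb * sig / mu_m + ph)
        Cc = np.pi * ra**2 * sig**2 / mu_m
        disc = np.maximum(B**2 - 4.0 * A * Cc, 0.0)
        root = (-B + np.sqrt(disc)) / (2.0 * A)  # the larger (physical) root
        C_hat[partial] = root

    liquid = mucus & (phi_hat > phi2)
    if np.any(liquid):
        ra, rb, ph = r_a[liquid], r_b[liquid], phi_hat[liquid]
        K1 = np.pi * ra**2 * (rb**2 - ra**2) / (4.0 * mu_m) + np.pi * ra**4 / (8.0 * mu_a)
        K0 = np.pi * ra**2 * sig * (rb - ra) / mu_m
        C_hat[liquid] = (ph + K0) / K1

    out = s * C_hat
    return float(out[0]) if scalar else out.reshape(np.shape(phi_air))


def _flows_core(C, r_a, r_b, fluids: FluidConstants):
    """Lean array-only forward map: (phi_air, phi_mucus) from gradients.

    No input validation or scalar sugar; used by the time stepper.
    """
    sig, mu_m, mu_a = fluids.sigma0, fluids.mu_mucus, fluids.mu_air
    s = np.sign(C)
    C_hat = np.abs(C)
    pos = C_hat > 0.0
    r0 = np.where(pos, 2.0 * sig / np.where(pos, C_hat, 1.0), np.inf)
    a = np.clip(r0, r_a, r_b)
    u_y = C_hat / (4.0 * mu_m) * (r_b**2 - a**2) - sig / mu_m * (r_b - a)
    np.maximum(u_y, 0.0, out=u_y)
    q_shear = C_hat * np.pi / (8.0 * mu_m) * (r_b**2 - a**2) ** 2 - (
        sig * np.pi / (3.0 * mu_m)
    ) * (r_b**3 - 3.0 * r_b * a**2 + 2.0 * a**3)
    np.maximum(q_shear, 0.0, out=q_shear)
    phi_m = u_y * np.pi * (a**2 - r_a**2) + q_shear
    phi_m[r0 >= r_b] = 0.0
    phi_a = u_y * np.pi * r_a**2 + C_hat * np.pi * r_a**4 / (8.0 * mu_a)
    return -s * phi_a, -s * phi_m


def _gradient_core(phi_air, r_a, r_b, fluids: FluidConstants, rigid_interface=False):
    """Lean array-only inverse map: gradients from air fluxes."""
    sig, mu_m, mu_a = fluids.sigma0, fluids.mu_mucus, fluids.mu_air
    s = -np.sign(phi_air)
    phi_hat = np.abs(phi_air)
    poise = np.pi * r_a**4 / (8.0 * mu_a)
    C_hat = phi_hat / poise
    if rigid_interface:
        return s * C_hat
    mucus = r_a < r_b * (1.0 - 1e-14)
    if not np.any(mucus):
        return s * C_hat
    phi1 = 2.0 * sig / r_b * poise
    phi2 = np.where(
        mucus,
        np.pi * r_a * sig * (r_b - r_a) ** 2 / (2.0 * mu_m)
        + sig * np.pi * r_a**3 / (4.0 * mu_a),
        np.inf,
    )
    partial = mucus & (phi_hat > phi1) & (phi_hat <= phi2)
    if np.any(partial):
        ra, rb, ph = r_a[partial], r_b[partial], phi_hat[partial]
        A = np.pi * ra**2 * rb**2 / (4.0 * mu_m) + np.pi * ra**4 / (8.0 * mu_a)
        B = -(np.pi * ra**2 * rb * sig / mu_m + ph)
        Cc = np.pi * ra**2 * sig**2 / mu_m
        disc = np.maximum(B**2 - 4.0 * A * Cc, 0.0)
        C_hat[partial] = (-B + np.sqrt(disc)) / (2.0 * A)
    liquid = mucus & (phi_hat > phi2)
    if np.any(liquid):
        ra, rb, ph = r_a[liquid], r_b[liquid], phi_hat[liquid]
        K1 = np.pi * ra**2 * (rb**2 - ra**2) / (4.0 * mu_m) + np.pi * ra**4 / (
            8.0 * mu_a
        )
        K0 = np.pi * ra**2 * sig * (rb - ra) / mu_m
        C_hat[liquid] = (ph + K0) / K1
    return s * C_hat


def airway_air_resistance(
    geom: AnnulusGeometry,
    fluids: FluidConstants | None = None,
    length: float = 1.0,
) -> float:
    """Per-airway air-core Poiseuille resistance 8 mu_a l / (pi r_a^4)."""
    fluids = fluids or FluidConstants()
    return 8.0 * fluids.mu_air * length / (np.pi * geom.r_a**4)


# ---------------------------------------------------------------------------
# Quadrature oracle (validation only; never called by the stepper)
# ---------------------------------------------------------------------------

def profile_oracle(
    C: float,
    geom: AnnulusGeometry,
    fluids: FluidConstants | None = None,
    tol: float = 1e-12,
) -> dict:
    """Fluxes by numerical integration of the velocity profile.

    Builds ``u(r)`` by integrating ``du/dr`` inward from the no-slip
    wall -- ``tau/mu_a`` in the air core, ``(tau - sigma0 sign(tau))/mu_m``
    in the yielded mucus, zero across the plug -- then integrates
    ``2 pi r u(r)`` for both fluxes with adaptive quadrature.
    """
    from scipy.integrate import quad

    fluids = fluids or FluidConstants()
    r_a, r_b = geom.r_a, geom.r_b
    if C == 0.0:
        return {"phi_air": 0.0, "phi_mucus": 0.0}
    sig, mu_m, mu_a = fluids.sigma0, fluids.mu_mucus, fluids.mu_air
    s = np.sign(C)

    def dudr_mucus(r):
        tau = C * r / 2.0
        if abs(tau) <= sig:
            return 0.0
        return (tau - sig * s) / mu_m

    r0 = yield_radius(C, sig)
    a = min(max(r0, r_a), r_b)

    def u_mucus(r):
        # u(r) = -int_r^{r_b} du/dr dr'
        val, _ = quad(dudr_mucus, r, r_b, epsabs=tol, epsrel=tol, points=[a])
        return -val

    u_interface = u_mucus(r_a) if r_b > r_a else 0.0

    def u_air(r):
        # du/dr = C r / (2 mu_a) in the core
        return u_interface - C * (r_a**2 - r**2) / (4.0 * mu_a)

    phi_m, _ = quad(
        lambda r: 2.0 * np.pi * r * u_mucus(r),
        r_a,
        r_b,
        epsabs=tol,
        epsrel=1e-10,
        points=[a],
        limit=200,
    )
    phi_a, _ = quad(
        lambda r: 2.0 * np.pi * r * u_air(r), 0.0, r_a, epsabs=tol, epsrel=1e-10
    )
    return {"phi_air": phi_a, "phi_mucus": phi_m}
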