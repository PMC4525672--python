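"""Static lung mechanics.

Three ingredients close the quasi-static mechanical model:

* the sigmoidal transmural pressure - lumen area law of the conducting
  airways (per-generation constants from the packaged table),
* a monotone static respiratory-system pressure-volume curve
  ``V_L,rs(dP)`` governing the acini, and a monotone lung tissue
  pressure curve ``P_tissue(V_L)`` providing the outer (distending)
  pressure on the airway walls,
* the lung-volume fixed point ``V_L = V_ac + V_tbt(V_L)`` coupling them.

The original static curves exist only as measured plots, so the default
``PVCurves`` are closed-form reconstructions anchored at the printed
quantities: ``V(0) = FRC = 3.25 L``, a rest compliance such that a
-5 cmH2O thoracic swing moves 0.5 L (the rest tidal volume), a tissue
pressure of 500 Pa at FRC and ~30 cmH2O near TLC.  User-supplied
tabulated curves can replace them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from mucodyn.tree_geometry import (
    N_CONDUCTING,
    AirwayGenerationSpec,
    LungVolumes,
    TreeSpec,
)
from mucodyn.units import from_cmH2O

DEFAULT_FRC_TRANSMURAL_PA = 500.0
DEFAULT_TLC_TISSUE_CMH2O = 30.0
DEFAULT_TIDAL_ANCHOR_CMH2O = 5.0


class OutOfDomainError(ValueError):
    """A pressure or volume fell outside the static-curve domain."""


class SolverFailure(RuntimeError):
    """The lung-volume fixed point could not be bracketed or refined."""


# ---------------------------------------------------------------------------
# Airway pressure-area law
# ---------------------------------------------------------------------------

def lambert_area(gen: AirwayGenerationSpec, dP: float) -> float:
    """Generation-summed lumen area (m^2) at transmural pressure ``dP``.

    The law is the two-branch sigmoid

    ``S(dP) = alpha0 (1 - dP/P1)^(-n1) A_m``            for ``dP <= 0``
    ``S(dP) = (1 - (1-alpha0)(1 - dP/P2)^(-n2)) A_m``   for ``dP > 0``

    with ``P1 = alpha0 n1 / alpha0'`` and
    ``P2 = -n2 (1 - alpha0) / alpha0'``.  It is C^1 at ``dP = 0`` (value
    ``alpha0 A_m``, slope ``alpha0' A_m`` from both branches), strictly
    increasing, and tends to ``A_m`` as ``dP -> +inf``.

    ``dP`` is distending: the tissue pressure around the wall minus the
    air pressure inside.
    """
    if not gen.is_conducting:
        raise ValueError("the airway pressure-area law applies to z <= 16 only")
    P1 = gen.alpha0 * gen.n1 / gen.alpha0_prime
    P2 = -gen.n2 * (1.0 - gen.alpha0) / gen.alpha0_prime
    if dP <= 0:
        return gen.alpha0 * (1.0 - dP / P1) ** (-gen.n1) * gen.A_m
    return (1.0 - (1.0 - gen.alpha0) * (1.0 - dP / P2) ** (-gen.n2)) * gen.A_m


#: Fraction of the zero-pressure area retained by a fully buckled airway.
#: The raw compressive branch of the pressure-area sigmoid assigns the
#: peripheral generations collapse pressures P1 of only a few Pa, so any
#: expiratory effort would pinch the model tree shut; real buckled
#: airways retain a patent lumen, and the quasi-static frame has no gas
#: trapping or reopening dynamics to handle full closure.  The live
#: mechanics therefore replace the compressive branch by an exponential
#: saturation matched in value and slope at zero transmural pressure,
#: decaying to ``MIN_AREA_FRAC * alpha0 * A_m``.
MIN_AREA_FRAC = 0.8


def lambert_area_vec(
    tree: TreeSpec, dP: np.ndarray, min_area_frac: float | None = None
) -> np.ndarray:
    """Vectorized pressure-area law over the 17 conducting generations.

    ``dP`` broadcasts against shape (17,); returns generation-summed
    areas in m^2.  For ``dP > 0`` this is the printed sigmoid; for
    ``dP <= 0`` the compressive branch is the C^1 saturation
    ``f + (alpha0 - f) exp(alpha0' dP / (alpha0 - f))`` with residual
    patency ``f = min_area_frac * alpha0`` (value ``alpha0 A_m`` and
    slope ``alpha0' A_m`` at zero are preserved exactly).
    """
    if min_area_frac is None:
        min_area_frac = MIN_AREA_FRAC
    dP = np.asarray(dP, dtype=float)
    f = min_area_frac * tree.alpha0
    span = tree.alpha0 - f
    neg = f + span * np.exp(tree.alpha0_prime * np.minimum(dP, 0.0) / span)
    pos = 1.0 - (1.0 - tree.alpha0) * (
        1.0 - np.maximum(dP, 0.0) / tree.P2
    ) ** (-tree.n2)
    return np.where(dP <= 0, neg, pos) * tree.A_m


def lambert_area_deriv_vec(
    tree: TreeSpec, dP: np.ndarray, min_area_frac: float | None = None
) -> np.ndarray:
    """d(area)/d(dP) of the vectorized law, m^2/Pa."""
    if min_area_frac is None:
        min_area_frac = MIN_AREA_FRAC
    dP = np.asarray(dP, dtype=float)
    f = min_area_frac * tree.alpha0
    span = tree.alpha0 - f
    dneg = tree.alpha0_prime * np.exp(
        tree.alpha0_prime * np.minimum(dP, 0.0) / span
    )
    dpos = (
        -(1.0 - tree.alpha0)
        * (tree.n2 / tree.P2)
        * (1.0 - np.maximum(dP, 0.0) / tree.P2) ** (-tree.n2 - 1.0)
    )
    return np.where(dP <= 0, dneg, dpos) * tree.A_m


# ---------------------------------------------------------------------------
# Static pressure-volume curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PVCurves:
    """Monotone static curves of the respiratory system.

    ``static_volume`` maps the airway-to-thorax pressure difference (Pa)
    to the static lung volume (m^3); ``tissue_pressure`` maps lung
    volume to the distending lung tissue pressure (Pa).
    """

    vols: LungVolumes
    static_volume: Callable[[np.ndarray], np.ndarray]
    static_volume_inv: Callable[[np.ndarray], np.ndarray]
    static_volume_deriv: Callable[[np.ndarray], np.ndarray]
    tissue_pressure: Callable[[np.ndarray], np.ndarray]
    tissue_pressure_deriv: Callable[[np.ndarray], np.ndarray]
    params: dict


def build_pv_curves(
    vols: LungVolumes | None = None,
    frc_transmural_pa: float = DEFAULT_FRC_TRANSMURAL_PA,
    tlc_tissue_cmH2O: float = DEFAULT_TLC_TISSUE_CMH2O,
    tidal_anchor_cmH2O: float = DEFAULT_TIDAL_ANCHOR_CMH2O,
    volume_table: np.ndarray | None = None,
    tissue_table: np.ndarray | None = None,
) -> PVCurves:
    """Build the static curves, by default from closed forms.

    Defaults: ``V(dP)`` is a logistic between the RV and TLC asymptotes
    calibrated so that ``V(0) = FRC`` and a ``tidal_anchor_cmH2O``
    pressure swing moves exactly the rest tidal volume (0.5 L), giving a
    rest compliance of ~0.1 L/cmH2O.  ``P_tissue(V)`` is an exponential
    recoil ``A (exp(k x) - 1)`` on the normalized volume
    ``x = (V - RV)/(TLC - RV)``, calibrated so that
    ``P_tissue(FRC) = frc_transmural_pa`` and
    ``P_tissue(TLC) = tlc_tissue_cmH2O``.

    ``volume_table``/``tissue_table``: optional ``(n, 2)`` arrays
    ``[pressure_cmH2O, volume_L]`` / ``[volume_L, pressure_cmH2O]``
    replacing a closed form with a strictly monotone PCHIP interpolant.
    """
    vols = vols or LungVolumes()
    RV, TLC, FRC = vols.RV, vols.TLC, vols.FRC
    span = TLC - RV
    params: dict = {"frc_transmural_pa": frc_transmural_pa}

    if volume_table is None:
        f0 = (FRC - RV) / span
        f1 = (FRC + vols.tidal_rest - RV) / span
        dP_a = from_cmH2O(tidal_anchor_cmH2O)
        # logit(f) = (dP - P_half)/P_scale
        p_scale = dP_a / (np.log(f1 / (1 - f1)) - np.log(f0 / (1 - f0)))
        p_half = -p_scale * np.log(f0 / (1 - f0))
        params.update(P_half=p_half, P_scale=p_scale)

        def static_volume(dP):
            return RV + span / (1.0 + np.exp(-(np.asarray(dP, float) - p_half) / p_scale))

        def static_volume_inv(V):
            V = np.asarray(V, float)
            if np.any(V <= RV) or np.any(V >= TLC):
                raise OutOfDomainError("volume outside (RV, TLC)")
            f = (V - RV) / span
            return p_half + p_scale * np.log(f / (1.0 - f))

        def static_volume_deriv(dP):
            e = np.exp(-(np.asarray(dP, float) - p_half) / p_scale)
            return span * e / (p_scale * (1.0 + e) ** 2)

    else:
        static_volume, static_volume_inv, static_volume_deriv = _tabulated(
            volume_table, pressure_first=True, vols=vols
        )

    if tissue_table is None:
        x0 = (FRC - RV) / span
        p_frc = frc_transmural_pa
        p_tlc = from_cmH2O(tlc_tissue_cmH2O)
        k = brentq(
            lambda kk: (np.expm1(kk) / np.expm1(kk * x0)) - p_tlc / p_frc,
            1e-6,
            50.0,
        )
        amp = p_frc / np.expm1(k * x0)
        params.update(tissue_k=k, tissue_amp=amp)

        def tissue_pressure(V):
            V = np.asarray(V, float)
            x = (V - RV) / span
            return amp * np.expm1(k * x)

        def tissue_pressure_deriv(V):
            V = np.asarray(V, float)
            x = (V - RV) / span
            return amp * k / span * np.exp(k * x)

    else:
        tissue_pressure, _, tissue_pressure_deriv = _tabulated(
            tissue_table, pressure_first=False, vols=vols
        )

    curves = PVCurves(
        vols=vols,
        static_volume=static_volume,
        static_volume_inv=static_volume_inv,
        static_volume_deriv=static_volume_deriv,
        tissue_pressure=tissue_pressure,
        tissue_pressure_deriv=tissue_pressure_deriv,
        params=params,
    )
    return curves


def _tabulated(table: np.ndarray, pressure_first: bool, vols: LungVolumes):
    """Monotone PCHIP interpolants from a two-column user table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 3:
        raise ValueError("curve table must be (n>=3, 2)")
    if pressure_first:
        x = from_cmH2O(table[:, 0])
        y = table[:, 1] * 1e-3  # L -> m^3
    else:
        x = table[:, 0] * 1e-3
        y = from_cmH2O(table[:, 1])
    if np.any(np.diff(x) <= 0) or np.any(np.diff(y) <= 0):
        raise ValueError("curve table must be strictly increasing in both columns")
    fwd = PchipInterpolator(x, y, extrapolate=False)
    inv = PchipInterpolator(y, x, extrapolate=False)
    der = fwd.derivative()

    def f(v):
        out = fwd(v)
        if np.any(np.isnan(out)):
            raise OutOfDomainError("value outside tabulated curve domain")
        return out

    def finv(v):
        out = inv(v)
        if np.any(np.isnan(out)):
            raise OutOfDomainError("value outside tabulated curve domain")
        return out

    def fder(v):
        out = der(v)
        if np.any(np.isnan(out)):
            raise OutOfDomainError("value outside tabulated curve domain")
        return out

    return f, finv, fder


# ---------------------------------------------------------------------------
# Tree volumes and the lung-volume fixed point
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcinarState:
    """Volumes of one alveolar duct unit (duct + its 58 alveoli)."""

    v_adu: float  # m^3
    duct_area: float  # m^2, per duct
    v_alv: float  # m^3, per alveolus


def tracheobronchial_volume(
    curves: PVCurves, tree: TreeSpec, V_L: float, P_air: np.ndarray
) -> float:
    """Conducting-airway volume (Eq. of the tree: sum of S_z * l_z).

    ``P_air`` holds at least the 17 conducting mid-airway pressures (Pa);
    areas are generation-summed, so no explicit 2**z factor appears.
    """
    vols = curves.vols
    if not vols.RV < V_L < vols.TLC:
        raise OutOfDomainError("lung volume outside (RV, TLC)")
    dP = curves.tissue_pressure(V_L) - np.asarray(P_air, float)[:N_CONDUCTING]
    areas = lambert_area_vec(tree, dP)
    return float(np.sum(areas * tree.lengths[:N_CONDUCTING]))


def _vtbt_open_glottis(curves: PVCurves, tree: TreeSpec, V: np.ndarray) -> np.ndarray:
    """Conducting volume at zero airway pressure, vectorized over volumes."""
    V = np.atleast_1d(np.asarray(V, dtype=float))
    dP = curves.tissue_pressure(V)[:, None]  # (n, 1) against (17,)
    areas = lambert_area_vec(tree, np.broadcast_to(dP, (V.size, N_CONDUCTING)))
    return areas @ tree.lengths[:N_CONDUCTING]


def alveolar_duct_units(
    curves: PVCurves, tree: TreeSpec, P_air_ac: np.ndarray, P_ext: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized acinar mechanics for generations 17..22.

    Returns ``(v_adu, duct_area, v_alv)`` arrays of length 6.  The inner
    conducting-tree volume is evaluated with zero airway pressure (the
    static reference configuration has atmospheric pressure across the
    whole tree).
    """
    x = np.asarray(P_air_ac, dtype=float) - P_ext
    V_rs = curves.static_volume(x)
    v_adu = (V_rs - _vtbt_open_glottis(curves, tree, V_rs)) / tree.n_adu_total
    duct_area = tree.alpha_duct * v_adu / tree.generations[17].length
    v_alv = (1.0 - tree.alpha_duct) * v_adu / tree.generations[17].n_alv
    return v_adu, duct_area, v_alv


def alveolar_duct_unit(
    curves: PVCurves, tree: TreeSpec, P_air_z: float, P_ext: float
) -> AcinarState:
    """Mechanics of a single alveolar duct unit at the given pressures."""
    v_adu, duct_area, v_alv = alveolar_duct_units(
        curves, tree, np.array([P_air_z]), P_ext
    )
    return AcinarState(
        v_adu=float(v_adu[0]), duct_area=float(duct_area[0]), v_alv=float(v_alv[0])
    )


def _acinar_volume(
    curves: PVCurves, tree: TreeSpec, P_air: np.ndarray, P_ext: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Total acinar volume plus the per-generation duct/alveolus arrays."""
    P_air = np.asarray(P_air, dtype=float)
    v_adu, duct_area, v_alv = alveolar_duct_units(
        curves, tree, P_air[N_CONDUCTING:], P_ext
    )
    mult = tree.multiplicity[N_CONDUCTING:]
    return float(np.sum(mult * v_adu)), duct_area, v_alv


def solve_lung_volume(
    curves: PVCurves,
    tree: TreeSpec,
    P_air: np.ndarray,
    P_ext: float,
    V_guess: float | None = None,
    tol: float = 1e-9,
    max_iter: int = 60,
) -> float:
    """Solve ``V_L = V_ac(P_air, P_ext) + V_tbt(V_L, P_air)``.

    Safeguarded Newton: a bisection bracket on (RV, TLC) backs up the
    Newton updates.  The solution is unique because the conducting-tree
    volume grows with ``V_L`` with slope well below one.
    """
    P_air = np.asarray(P_air, dtype=float)
    V_ac, _, _ = _acinar_volume(curves, tree, P_air, P_ext)
    return _solve_vl_given_vac(curves, tree, P_air, V_ac, V_guess, tol, max_iter)


def _solve_vl_given_vac(
    curves: PVCurves,
    tree: TreeSpec,
    P_air: np.ndarray,
    V_ac: float,
    V_guess: float | None = None,
    tol: float = 1e-9,
    max_iter: int = 60,
) -> float:
    vols = curves.vols
    eps = 1e-12
    lo, hi = vols.RV + 1e-7, vols.TLC - 1e-7
    lengths = tree.lengths[:N_CONDUCTING]
    P_cond = P_air[:N_CONDUCTING]

    def residual_and_deriv(V):
        pt = curves.tissue_pressure(V)
        dP = pt - P_cond
        areas = lambert_area_vec(tree, dP)
        vtbt = float(areas @ lengths)
        dvtbt = float(
            (lambert_area_deriv_vec(tree, dP) @ lengths)
            * curves.tissue_pressure_deriv(V)
        )
        return V - V_ac - vtbt, 1.0 - dvtbt

    g_lo, _ = residual_and_deriv(lo)
    g_hi, _ = residual_and_deriv(hi)
    if g_lo > 0 and g_hi > 0 or g_lo < 0 and g_hi < 0:
        raise SolverFailure(
            f"no sign change on (RV, TLC): g(RV)={g_lo:.3e}, g(TLC)={g_hi:.3e}, "
            f"V_ac={V_ac:.6e}"
        )
    if g_lo > 0:  # ensure g(lo) < 0 < g(hi)
        lo, hi, g_lo, g_hi = hi, lo, g_hi, g_lo

    V = V_guess if V_guess is not None else curves.vols.FRC
    if not (min(lo, hi) < V < max(lo, hi)):
        V = 0.5 * (lo + hi)
    for _ in range(max_iter):
        g, dg = residual_and_deriv(V)
        if abs(g) < tol:
            return float(V)
        if g < 0:
            lo = V
        else:
            hi = V
        if dg > eps:
            V_new = V - g / dg
        else:
            V_new = 0.5 * (lo + hi)
        if not (min(lo, hi) < V_new < max(lo, hi)):
            V_new = 0.5 * (lo + hi)
        V = V_new
    raise SolverFailure(f"lung-volume solve did not reach |residual| < {tol}")


def mechanics_map(
    curves: PVCurves,
    tree: TreeSpec,
    P_ext: float,
    P_air: np.ndarray,
    V_guess: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bronchus lumen areas for all 23 generations (generation-summed).

    Returns ``(S_b, v_alv, V_L)``: conducting areas from the
    pressure-area law at the solved lung volume, acinar duct areas from
    the duct-unit decomposition, per-alveolus volumes for generations
    17..22, and the solved lung volume.
    """
    P_air = np.asarray(P_air, dtype=float)
    V_ac, duct_area, v_alv = _acinar_volume(curves, tree, P_air, P_ext)
    V_L = _solve_vl_given_vac(curves, tree, P_air, V_ac, V_guess)
    dP = curves.tissue_pressure(V_L) - P_air[:N_CONDUCTING]
    S_b = np.empty(23)
    S_b[:N_CONDUCTING] = lambert_area_vec(tree, dP)
    S_b[N_CONDUCTING:] = duct_area * tree.multiplicity[N_CONDUCTING:]
    return S_b, v_alv, float(V_L)
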