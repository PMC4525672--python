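"""Scalar outcome measures of a maneuver.

* ``v_out`` -- cumulative mucus volume expelled through the trachea.
* ``r`` -- FRC-referenced relative hydrodynamic resistance: the
  air-core Poiseuille resistance of the conducting tree evaluated with
  pressures reset to rest but the *current* mucus distribution, divided
  by its pre-maneuver value (so ``r(0) = 1`` by construction).
* ``mmp`` -- mean mucus position: the mucus-volume-weighted mean
  generation index; expelled volume enters the numerator with weight
  -1 (above the trachea).
* Shrek number -- the average over the conducting generations of the
  air shear stress at the mucus interface over the yield stress
  ``sigma0``; its time average measures mobilization efficiency.
* comfort number -- time-averaged relative shift of the lung tissue
  pressure with respect to a quiet-breathing reference run.
"""

from __future__ import annotations

import numpy as np

from mucodyn.constitutive import PVCurves, mechanics_map
from mucodyn.tree_geometry import N_CONDUCTING, N_GENERATIONS, TreeSpec
from mucodyn.two_phase_flow import FluidConstants

DEFAULT_SHREK_GENERATIONS = N_CONDUCTING  # average over the conducting tree


# ---------------------------------------------------------------------------
# Hydrodynamic resistance
# ---------------------------------------------------------------------------

def tree_resistance(
    tree: TreeSpec,
    S_a: np.ndarray,
    fluids: FluidConstants | None = None,
) -> float:
    """Air-core resistance of the conducting tree (Pa s/m^3).

    Series across generations, parallel within a generation:
    ``R = sum_z R_airway(z) / 2**z`` with per-airway Poiseuille
    resistance ``8 mu_a l_z / (pi r_a^4)``.  ``S_a`` holds
    generation-summed air lumen areas (first 17 entries used).
    """
    fluids = fluids or FluidConstants()
    n = N_CONDUCTING
    mult = tree.multiplicity[:n]
    s_per = np.asarray(S_a, dtype=float)[:n] / mult
    if np.any(s_per <= 0):
        raise ValueError("degenerate air lumen area")
    r4 = (s_per / np.pi) ** 2  # r^4 = (S/pi)^2
    R_per = 8.0 * fluids.mu_air * tree.lengths[:n] / (np.pi * r4)
    return float(np.sum(R_per / mult))


def resistance_from_mucus(
    tree: TreeSpec,
    S_b_rest: np.ndarray,
    mucus_volumes: np.ndarray,
    fluids: FluidConstants | None = None,
    r_a_floor_frac: float = 1e-2,
) -> float:
    """FRC-referenced resistance: rest-state walls, given mucus load."""
    n = N_CONDUCTING
    S_b = np.asarray(S_b_rest, dtype=float)[:n]
    S_a = S_b - np.asarray(mucus_volumes, dtype=float) / tree.lengths[:n]
    S_a = np.maximum(S_a, r_a_floor_frac**2 * S_b)
    return tree_resistance(tree, S_a, fluids)


def relative_resistance(
    state,
    baseline,
    tree: TreeSpec,
    curves: PVCurves,
    fluids: FluidConstants | None = None,
    r_a_floor_frac: float = 1e-2,
) -> float:
    """Relative FRC-referenced resistance of ``state`` vs ``baseline``.

    Both states are re-evaluated on the rest-state tree (chest and
    airway pressures zero) carrying each state's own mucus volumes, so
    the ratio isolates mucus redistribution from wall deformation.
    """
    S_b_rest, _, _ = mechanics_map(curves, tree, 0.0, np.zeros(N_GENERATIONS))
    R = resistance_from_mucus(
        tree, S_b_rest, state.mucus_volumes(tree), fluids, r_a_floor_frac
    )
    R0 = resistance_from_mucus(
        tree, S_b_rest, baseline.mucus_volumes(tree), fluids, r_a_floor_frac
    )
    return R / R0


# ---------------------------------------------------------------------------
# Mean mucus position
# ---------------------------------------------------------------------------

def mean_mucus_position(state, tree: TreeSpec) -> float:
    """Mucus-volume-weighted mean generation index.

    ``mmp = (-v_out + sum_z z Vm_z) / (v_out + sum_z Vm_z)`` with
    generation-summed mucus volumes ``Vm_z``; expelled volume counts
    with weight -1.
    """
    Vm = state.mucus_volumes(tree)
    v_out = state.v_out
    denom = v_out + float(np.sum(Vm))
    if denom <= 0:
        raise ValueError("mean mucus position undefined: no mucus anywhere")
    z = np.arange(N_CONDUCTING)
    return float((-v_out + np.sum(z * Vm)) / denom)


# ---------------------------------------------------------------------------
# Shrek number
# ---------------------------------------------------------------------------

def instantaneous_shrek(
    tree: TreeSpec,
    phi_a: np.ndarray,
    S_a: np.ndarray,
    fluids: FluidConstants | None = None,
    n_generations: int = DEFAULT_SHREK_GENERATIONS,
) -> float:
    """Average over generations of |air shear at the interface| / sigma0.

    The shear exerted on the mucus by a per-airway air flow ``phi`` in a
    core of radius ``r_a`` is ``4 mu_a phi / (pi r_a^3)``; flow
    magnitudes are used so that inspiration and expiration both count.
    """
    fluids = fluids or FluidConstants()
    n = n_generations
    mult = tree.multiplicity[:n]
    s_per = np.asarray(S_a, dtype=float)[:n] / mult
    r3 = (s_per / np.pi) ** 1.5
    tau = 4.0 * fluids.mu_air * np.abs(np.asarray(phi_a, dtype=float)[:n]) / (np.pi * r3)
    return float(np.mean(tau) / fluids.sigma0)


def shrek(
    result,
    fluids: FluidConstants | None = None,
    n_generations: int = DEFAULT_SHREK_GENERATIONS,
) -> dict:
    """Shrek numbers of a run: instantaneous trace, approximation, mean.

    ``iSh`` is the recorded instantaneous trace; ``iSh_approx`` the
    resistance-based shortcut ``R_aw |phi_mouth| / (12 N sigma0)``
    (exact if every airway had a length-to-diameter ratio of 3);
    ``Sh`` the trapezoidal time average of ``iSh`` over the run.
    """
    fluids = fluids or result.fluids
    iSh = np.asarray(result.iSh, dtype=float)
    T = result.times[-1] - result.times[0]
    Sh = float(np.trapezoid(iSh, result.times) / T) if T > 0 else float(iSh[0])
    iSh_approx = (
        np.asarray(result.R_inst, dtype=float)
        * np.abs(result.phi_mouth)
        / (12.0 * n_generations * fluids.sigma0)
    )
    return {"iSh": iSh, "iSh_approx": iSh_approx, "Sh": Sh}


def compliance_shrek(
    result,
    fluids: FluidConstants | None = None,
    n_generations: int = DEFAULT_SHREK_GENERATIONS,
) -> np.ndarray:
    """Diagnostic Shrek estimate from trace compliance.

    Uses ``C_L = dV_L / dP_ext`` measured over each recorded interval
    and ``iSh ~ C_L R_aw |dP_ext/dt| / (12 N sigma0)``; intervals with
    no chest-pressure change yield NaN.
    """
    fluids = fluids or result.fluids
    dV = np.diff(result.V_L)
    dP = np.diff(result.P_ext)
    dt = np.diff(result.times)
    with np.errstate(divide="ignore", invalid="ignore"):
        # compliance as a magnitude: positive chest pressure deflates
        C_L = np.where(dP != 0, np.abs(dV / dP), np.nan)
        rate = dP / dt
    Raw = 0.5 * (np.asarray(result.R_inst)[1:] + np.asarray(result.R_inst)[:-1])
    return C_L * Raw * np.abs(rate) / (12.0 * n_generations * fluids.sigma0)


# ---------------------------------------------------------------------------
# Comfort number
# ---------------------------------------------------------------------------

def comfort(result, reference) -> dict:
    """Comfort number of a run against its quiet-breathing reference.

    Both runs must share the time grid.  ``iCom(t)`` is the absolute
    relative shift of the lung tissue pressure; ``Com`` its trapezoidal
    time average over the run.
    """
    if result.times.shape != reference.times.shape or np.any(
        np.abs(result.times - reference.times) > 1e-9
    ):
        raise ValueError("comfort requires matching time grids")
    curves = result.curves
    p = curves.tissue_pressure(result.V_L)
    p_ref = curves.tissue_pressure(reference.V_L)
    iCom = np.abs((p - p_ref) / p_ref)
    T = result.times[-1] - result.times[0]
    Com = float(np.trapezoid(iCom, result.times) / T) if T > 0 else float(iCom[0])
    return {"iCom": iCom, "Com": Com}
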