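"""Coupled quasi-static dynamics on the bronchial tree.

One implicit (backward-Euler) step advances the full lung state under a
prescribed chest pressure ``P_ext``.  The unknown of the step is the
23-vector of mid-airway air pressures ``P_air``; everything else is
slaved to it:

1. wall mechanics gives bronchus areas, alveolar volumes and the lung
   volume (an inner scalar Newton solve of the volume fixed point);
2. backward differences give the area/volume rates, and the air
   conservation law is accumulated leaf-to-root into per-airway flows;
3. the two-phase closure converts each flow into a pressure gradient,
   and the Bingham mucus fluxes redistribute the mucus cross-sections
   (iterated to self-consistency in the fully-implicit mode);
4. the gradients are summed root-to-leaf into implied mid-airway
   pressures; the residual is the mismatch with the candidate vector.

The residual is zeroed by a damped quasi-Newton iteration: a
finite-difference Jacobian reused across steps and kept current with
Broyden rank-one updates, a backtracking line search, a nonmonotone
rescue step at semismooth (yield/floor) kinks, and adaptive step
bisection on failure.  There is no randomness anywhere: a run is a
deterministic function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mucodyn.constitutive import PVCurves, build_pv_curves, mechanics_map
from mucodyn.maneuvers import ManeuverSpec, external_pressure
from mucodyn.metrics import instantaneous_shrek, resistance_from_mucus, tree_resistance
from mucodyn.tree_geometry import N_CONDUCTING, N_GENERATIONS, TreeSpec, build_tree_spec
from mucodyn.two_phase_flow import (
    FluidConstants,
    _flows_core,
    _gradient_core,
)


class StepFailure(RuntimeError):
    """A time step did not converge; carries the residual history."""

    def __init__(self, msg: str, history: list[float] | None = None):
        super().__init__(msg)
        self.history = history or []


@dataclass
class StepperConfig:
    """Numerical settings of the implicit stepper."""

    dt: float = 5e-3  # s
    newton_tol: float = 1e-4  # Pa, max-norm of the pressure residual
    newton_tol_soft: float = 1e-2  # Pa, stagnation acceptance floor
    newton_tol_soft_rel: float = 5e-3  # stagnation acceptance, fraction of |P|
    max_iter: int = 150
    damping: float = 1.0
    r_a_floor_frac: float = 0.1  # air-core radius floor, fraction of r_b
    mucus_mode: str = "implicit"  # implicit | semi-implicit
    inner_tol: float = 1e-16  # m^3, mucus fixed-point tolerance
    inner_max_iter: int = 20
    jacobian_refresh_iters: int = 10  # iterations between FD Jacobian refreshes
    rigid_interface: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.newton_tol <= 0 or self.inner_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.mucus_mode not in ("implicit", "semi-implicit"):
            raise ValueError("mucus_mode must be 'implicit' or 'semi-implicit'")


@dataclass
class LungState:
    """Instantaneous state of the lung (generation-summed areas)."""

    t: float
    S_a: np.ndarray  # (23,) air lumen areas, m^2
    S_b: np.ndarray  # (23,) bronchus lumen areas, m^2
    v_alv: np.ndarray  # (6,) per-alveolus volumes, generations 17..22, m^3
    P_air: np.ndarray  # (23,) mid-airway pressures, Pa
    V_L: float  # m^3
    v_out: float = 0.0  # cumulative expelled mucus, m^3
    phi_a: np.ndarray = field(default_factory=lambda: np.zeros(N_GENERATIONS))
    C: np.ndarray = field(default_factory=lambda: np.zeros(N_GENERATIONS))
    #: generation-summed mucus volumes in the conducting generations, m^3.
    #: Carried explicitly: when an airway squeezes onto its mucus the air
    #: lumen is floored for the hydraulics, so (S_b - S_a) l would leak mass.
    Vm: np.ndarray = field(default_factory=lambda: np.zeros(N_CONDUCTING))

    def mucus_volumes(self, tree: TreeSpec | None = None) -> np.ndarray:
        """Generation-summed mucus volumes (m^3) in the 17 conducting gens."""
        return self.Vm

    def copy(self) -> "LungState":
        return LungState(
            t=self.t,
            S_a=self.S_a.copy(),
            S_b=self.S_b.copy(),
            v_alv=self.v_alv.copy(),
            P_air=self.P_air.copy(),
            V_L=self.V_L,
            v_out=self.v_out,
            phi_a=self.phi_a.copy(),
            C=self.C.copy(),
            Vm=self.Vm.copy(),
        )


@dataclass
class SimulationResult:
    """Recorded traces of a run plus the final state and model objects."""

    times: np.ndarray
    P_ext: np.ndarray
    V_L: np.ndarray
    v_out: np.ndarray
    phi_mouth: np.ndarray  # air flow at the tree root (up-tree positive), m^3/s
    iSh: np.ndarray  # instantaneous Shrek number
    r: np.ndarray  # FRC-referenced relative resistance
    R_inst: np.ndarray  # instantaneous air-core tree resistance, Pa s/m^3
    mmp: np.ndarray  # mean mucus position, generation index
    mucus_volumes: np.ndarray  # (n_rec, 17), generation-summed, m^3
    final_state: LungState
    initial_state: LungState
    tree: TreeSpec
    curves: PVCurves
    fluids: FluidConstants
    cfg: StepperConfig
    maneuver: ManeuverSpec | None = None
    newton_iterations: int = 0
    clamp_events: int = 0
    soft_accepts: int = 0
    substep_events: int = 0
    completed: bool = True


def _floored_air_area(
    S_b_cond: np.ndarray,
    Vm: np.ndarray,
    lengths: np.ndarray,
    floor_area: float,
) -> np.ndarray:
    """Air lumen areas with a C^1 floor at the occlusion guard.

    Mucus in excess of the wall volume is conserved, not destroyed: the
    geometric identity ``S_a = S_b - Vm/l`` is relaxed while an airway
    is squeezed onto its mucus.
    """
    raw = S_b_cond - Vm / lengths
    lo = floor_area * S_b_cond
    w = 0.5 * lo  # blend width, well below any open-lumen scale
    out = 0.5 * (raw + lo + np.sqrt((raw - lo) ** 2 + w * w))
    return np.minimum(out, S_b_cond)


class _Stepper:
    """Residual assembly and quasi-Newton driver for one model instance."""

    def __init__(
        self,
        tree: TreeSpec,
        curves: PVCurves,
        fluids: FluidConstants,
        cfg: StepperConfig,
    ):
        self.tree = tree
        self.curves = curves
        self.fluids = fluids
        self.cfg = cfg
        n = N_CONDUCTING
        self.mult = tree.multiplicity
        self.mult_cond = tree.multiplicity[:n]
        self.lengths = tree.lengths
        self.l_cond = tree.lengths[:n]
        self.n_alv = np.array([g.n_alv for g in tree.generations], dtype=float)
        self._J = None
        self._jac_dt = None
        # compiled fast path for the closed-form default curves
        self._fast = False
        p = curves.params
        if all(k in p for k in ("P_half", "P_scale", "tissue_amp", "tissue_k")):
            from mucodyn import _kernels
            from mucodyn.constitutive import MIN_AREA_FRAC

            self._tree_c, self._scal = _kernels.pack_constants(
                tree, curves, fluids, cfg, MIN_AREA_FRAC
            )
            self._kernel = _kernels.residual_kernel
            self._fast = True
        self.newton_iterations = 0
        self.clamp_events = 0
        self.soft_accepts = 0
        self.substep_events = 0

    # -- residual ----------------------------------------------------------

    def residual(
        self, P: np.ndarray, P_ext: float, prev: LungState, dt: float | None = None
    ) -> tuple:
        """Pressure residual at candidate ``P``; returns (res, stash)."""
        if self._fast:
            dt_ = self.cfg.dt if dt is None else dt
            ok, res, S_b, S_a, v_alv, V_L, C, phi, phi_m, Vm, occl = (
                self._kernel(
                    np.asarray(P, dtype=float), float(P_ext), prev.S_a,
                    prev.v_alv, prev.Vm, prev.V_L, dt_, self._tree_c,
                    self._scal,
                )
            )
            if ok != 0:
                raise ValueError("lung-volume fixed point not solvable here")
            stash = {
                "S_b": S_b, "S_a": S_a, "v_alv": v_alv, "V_L": float(V_L),
                "C": C, "phi": phi, "phi_m": phi_m, "Vm": Vm,
                "clamped": int(occl),
            }
            return res, stash
        return self._residual_numpy(P, P_ext, prev, dt)

    def _residual_numpy(
        self, P: np.ndarray, P_ext: float, prev: LungState, dt: float | None = None
    ) -> tuple:
        """Reference numpy residual (also serves user-tabulated curves)."""
        cfg, tree, fluids = self.cfg, self.tree, self.fluids
        dt = cfg.dt if dt is None else dt
        n = N_CONDUCTING
        S_b, v_alv, V_L = mechanics_map(
            self.curves, tree, P_ext, P, V_guess=prev.V_L
        )
        phi_alv = -(v_alv - prev.v_alv) / dt  # per alveolus, m^3/s

        Vm_prev = prev.mucus_volumes()
        floor_area = cfg.r_a_floor_frac**2
        avail_lim = Vm_prev / (self.mult_cond * dt)  # max per-airway outflow

        S_a = S_b.copy()  # acinar: no mucus
        dSdt_ac = (S_b[n:] - prev.S_a[n:]) / dt
        Vm = Vm_prev
        inner_max = cfg.inner_max_iter if cfg.mucus_mode == "implicit" else 1
        inner_tol = max(cfg.inner_tol, 1e-9 * float(np.max(Vm, initial=0.0)))

        S_b_cond = S_b[:n]
        r_b = np.sqrt(S_b / self.mult / np.pi)
        prev_Sa_cond = prev.S_a[:n]

        def air_area(vm: np.ndarray) -> np.ndarray:
            return _floored_air_area(S_b_cond, vm, self.l_cond, floor_area)

        for _ in range(inner_max):
            S_a_cond = air_area(Vm)
            dSdt = np.concatenate(((S_a_cond - prev_Sa_cond) / dt, dSdt_ac))
            phi = self._tree_flows(dSdt, phi_alv)
            r_a = np.sqrt(np.concatenate((S_a_cond, S_b[n:])) / self.mult / np.pi)
            C = _gradient_core(-phi, r_a, r_b, fluids, cfg.rigid_interface)
            _, phi_m = _flows_core(C[:n], r_a[:n], r_b[:n], fluids)
            phi_m[n - 1] = min(phi_m[n - 1], 0.0)  # mucus cannot enter the acini
            # C^1 saturation at the available-mucus limit (a hard clip puts
            # the congested solution exactly on a kink)
            phi_m = phi_m * avail_lim / (np.abs(phi_m) + avail_lim + 1e-300)
            inflow = np.zeros(n)
            inflow[1:] += 0.5 * np.maximum(phi_m[:-1], 0.0)
            inflow[:-1] += -2.0 * np.minimum(phi_m[1:], 0.0)
            Vm_new = Vm_prev + self.mult_cond * (inflow - np.abs(phi_m)) * dt
            np.maximum(Vm_new, 0.0, out=Vm_new)
            delta = float(np.max(np.abs(Vm_new - Vm)))
            Vm = Vm_new
            if delta < inner_tol:
                break

        clamped = int(np.count_nonzero(S_b_cond * self.l_cond < Vm))
        S_a[:n] = air_area(Vm)
        Cl = C * self.lengths
        P_implied = np.concatenate(([0.0], np.cumsum(Cl)[:-1])) + 0.5 * Cl
        res = P - P_implied
        stash = {
            "S_b": S_b,
            "S_a": S_a,
            "v_alv": v_alv,
            "V_L": V_L,
            "C": C,
            "phi": phi,
            "phi_m": phi_m,
            "Vm": Vm,
            "clamped": clamped,
        }
        return res, stash

    def _tree_flows(self, dSdt: np.ndarray, phi_alv: np.ndarray) -> np.ndarray:
        """Leaf-to-root air flow recursion (per-airway, up-tree positive).

        Mass balance of the air in one airway: its volume grows by the
        inflow from the daughters minus the outflow at the top minus
        what the attached alveoli absorb, so
        ``phi[z] = 2 phi[z+1] - dS_a/dt l - n_alv dv_alv/dt``.  At the
        root this telescopes to minus the rate of change of the total
        gas volume (inspiration: negative mouth flow).
        """
        n = N_CONDUCTING
        phi = np.empty(N_GENERATIONS)
        child = 0.0
        for z in range(N_GENERATIONS - 1, -1, -1):
            own = -dSdt[z] / self.mult[z] * self.lengths[z]
            alv = self.n_alv[z] * phi_alv[z - n] if z >= n else 0.0
            phi[z] = own + 2.0 * child + alv
            child = phi[z]
        return phi

    # -- Newton driver -----------------------------------------------------

    _P_BOUND = 5e4  # Pa, hard guard on candidate mid-airway pressures

    def _try_residual(self, P: np.ndarray, P_ext: float, prev: LungState, dt: float):
        """Residual or ``None`` when the candidate leaves the model domain."""
        try:
            res, stash = self.residual(P, P_ext, prev, dt)
        except (ValueError, ArithmeticError, RuntimeError):
            return None
        self.newton_iterations += 1
        if not np.all(np.isfinite(res)):
            return None
        return res, stash

    def _fd_jacobian(
        self, P: np.ndarray, P_ext: float, prev: LungState, dt: float
    ) -> bool:
        out = self._try_residual(P, P_ext, prev, dt)
        if out is None:
            return False
        r0, _ = out
        J = np.eye(N_GENERATIONS)
        for j in range(N_GENERATIONS):
            h = 1e-3 * max(1.0, abs(P[j]) * 1e-3)
            Pj = P.copy()
            Pj[j] += h
            col = self._try_residual(Pj, P_ext, prev, dt)
            if col is not None:
                J[:, j] = (col[0] - r0) / h
        if not np.all(np.isfinite(J)):
            return False
        self._J = J
        self._jac_dt = dt
        return True

    def _newton_delta(self, res: np.ndarray) -> np.ndarray:
        try:
            delta = np.linalg.solve(self._J, -res)
        except np.linalg.LinAlgError:
            delta = -res
        if not np.all(np.isfinite(delta)):
            delta = -res
        return delta

    def solve_step(
        self, prev: LungState, P_ext: float, dt: float | None = None
    ) -> tuple[np.ndarray, dict, list[float]]:
        """Damped quasi-Newton with backtracking and fixed-point fallback.

        The finite-difference Jacobian is reused across steps and kept
        current with Broyden rank-one updates; a full refresh happens
        when the line search fails or progress stalls.  Steps whose
        residual stagnates below ``newton_tol_soft`` (the noise floor of
        the inner mucus fixed point) are accepted and counted.
        """
        cfg = self.cfg
        dt = cfg.dt if dt is None else dt
        P = prev.P_air.copy()
        out = self._try_residual(P, P_ext, prev, dt)
        if out is None:
            raise StepFailure("residual undefined at the previous pressures")
        res, stash = out
        nr = float(np.max(np.abs(res)))
        history: list[float] = [nr]
        best = (P, stash, nr)
        if self._J is None or self._jac_dt != dt:
            self._fd_jacobian(P, P_ext, prev, dt)
        need_refresh = False
        fresh = False
        no_progress = 0
        for it in range(cfg.max_iter):
            if nr < cfg.newton_tol:
                return P, stash, history
            soft = max(
                cfg.newton_tol_soft,
                cfg.newton_tol_soft_rel * float(np.max(np.abs(P))),
            )
            if nr < soft and it >= 6:
                recent = history[-3:]
                if recent[-1] > 0.5 * recent[0]:
                    self.soft_accepts += 1  # stagnating at the noise floor
                    return P, stash, history
            if need_refresh:
                fresh = self._fd_jacobian(P, P_ext, prev, dt)
                need_refresh = False
            delta = self._newton_delta(res)
            lam = cfg.damping
            accepted = None
            fallback = None  # best finite candidate even if not descending
            for _ in range(10):  # backtracking line search
                P_try = np.clip(P + lam * delta, -self._P_BOUND, self._P_BOUND)
                out = self._try_residual(P_try, P_ext, prev, dt)
                if out is not None:
                    nr_try = float(np.max(np.abs(out[0])))
                    if nr_try < nr or nr_try < cfg.newton_tol:
                        accepted = (P_try, out, nr_try, lam)
                        break
                    if fallback is None or nr_try < fallback[2]:
                        fallback = (P_try, out, nr_try, lam)
                lam *= 0.5
            if accepted is None:
                if not fresh:
                    need_refresh = True  # retry from a fresh Jacobian
                    continue
                # fresh Jacobian and still no descent: the residual is at a
                # kink.  Take the least-bad finite candidate (nonmonotone
                # rescue) rather than giving up outright.
                if fallback is not None and fallback[2] < 3.0 * nr:
                    accepted = fallback
                    need_refresh = True
                else:
                    break
            P_new, (res_new, stash), nr_new, lam = accepted
            step = P_new - P
            dres = res_new - res
            denom = float(step @ step)
            if denom > 0:  # Broyden good update keeps J current cheaply
                self._J = self._J + np.outer(dres - self._J @ step, step) / denom
            if nr_new > 0.5 * nr or lam < cfg.damping:
                need_refresh = True
            else:
                fresh = False
            P, res, nr = P_new, res_new, nr_new
            history.append(nr)
            if nr < 0.99 * best[2]:
                best = (P, stash, nr)
                no_progress = 0
            else:
                no_progress += 1
                if no_progress >= 15:
                    break  # bouncing around a kink without gaining ground
        if nr < cfg.newton_tol:
            return P, stash, history
        soft = max(
            cfg.newton_tol_soft,
            cfg.newton_tol_soft_rel * float(np.max(np.abs(best[0]))),
        )
        if best[2] < soft:
            self.soft_accepts += 1
            return best[0], best[1], history
        raise StepFailure(
            f"step did not converge below {cfg.newton_tol} Pa "
            f"(best residual {best[2]:.3e} Pa in {len(history)} iterations)",
            history,
        )

    def advance(
        self, prev: LungState, P_ext_next: float, dt: float | None = None
    ) -> LungState:
        dt = self.cfg.dt if dt is None else dt
        P, stash, _ = self.solve_step(prev, P_ext_next, dt)
        self.clamp_events += stash["clamped"]
        n = N_CONDUCTING
        v_out = prev.v_out
        phi_m0 = stash["phi_m"][0]
        if phi_m0 < 0.0:
            v_out += -phi_m0 * dt  # trachea outflow (2**0 airways)
        return LungState(
            t=prev.t + dt,
            S_a=stash["S_a"],
            S_b=stash["S_b"],
            v_alv=stash["v_alv"],
            P_air=P,
            V_L=stash["V_L"],
            v_out=v_out,
            phi_a=stash["phi"],
            C=stash["C"],
            Vm=stash["Vm"],
        )

    def advance_adaptive(
        self,
        prev: LungState,
        t_prev: float,
        t_next: float,
        p_ext_of_t,
        max_depth: int = 8,
    ) -> LungState:
        """Advance over ``[t_prev, t_next]``, bisecting dt on step failure.

        Stiff transients (airway collapse onset, yield transitions) can
        defeat the Newton solve at the nominal dt; halving the step and
        re-integrating the sub-intervals tracks the transition.
        """
        try:
            return self.advance(prev, p_ext_of_t(t_next), dt=t_next - t_prev)
        except StepFailure:
            if max_depth <= 0:
                raise
            self.substep_events += 1
            mid = 0.5 * (t_prev + t_next)
            s = self.advance_adaptive(prev, t_prev, mid, p_ext_of_t, max_depth - 1)
            return self.advance_adaptive(s, mid, t_next, p_ext_of_t, max_depth - 1)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def mucus_inflow(phi_m_out: np.ndarray, z: int) -> float:
    """Mucus inflow into generation ``z`` from its neighbours (m^3/s).

    Per-airway balance: half of a downward parent flux, twice an upward
    daughter flux; contributions of the wrong sign are ignored.  The
    trachea has no parent term and generation 16 no daughter term.
    """
    if z >= N_CONDUCTING:
        raise ValueError("mucus is confined to the conducting generations")
    inflow = 0.0
    if z > 0:
        inflow += 0.5 * max(0.0, float(phi_m_out[z - 1]))
    if z < N_CONDUCTING - 1:
        inflow += -2.0 * min(0.0, float(phi_m_out[z + 1]))
    return inflow


def step_residual(
    prev: LungState,
    P_air_candidate: np.ndarray,
    P_ext: float,
    cfg: StepperConfig,
    tree: TreeSpec | None = None,
    curves: PVCurves | None = None,
    fluids: FluidConstants | None = None,
) -> np.ndarray:
    """Pressure residual of one backward-Euler step at a candidate P_air."""
    tree = tree or build_tree_spec()
    curves = curves or build_pv_curves()
    fluids = fluids or FluidConstants()
    stepper = _Stepper(tree, curves, fluids, cfg)
    res, _ = stepper.residual(np.asarray(P_air_candidate, float), P_ext, prev)
    return res


def advance(
    prev: LungState,
    P_ext_next: float,
    cfg: StepperConfig,
    tree: TreeSpec | None = None,
    curves: PVCurves | None = None,
    fluids: FluidConstants | None = None,
) -> LungState:
    """One implicit step of the coupled system (standalone convenience)."""
    tree = tree or build_tree_spec()
    curves = curves or build_pv_curves()
    fluids = fluids or FluidConstants()
    return _Stepper(tree, curves, fluids, cfg).advance(prev, P_ext_next)


def find_rest_state(
    curves: PVCurves,
    tree: TreeSpec,
    fixture,
    fluids: FluidConstants | None = None,
    cfg: StepperConfig | None = None,
) -> LungState:
    """Equilibrium state at zero chest and airway pressures.

    ``fixture`` is a mucus profile (anything with a 17-entry
    ``fill_array`` attribute, or a bare array of fill fractions in
    ``[0, 1)``) applied to the rest-state bronchus areas.
    """
    fill = getattr(fixture, "fill_array", None)
    if fill is None:
        fill = np.asarray(fixture, dtype=float)
    if fill.shape != (N_CONDUCTING,) or np.any(fill < 0) or np.any(fill >= 1):
        raise ValueError("mucus fill must be 17 fractions in [0, 1)")
    P = np.zeros(N_GENERATIONS)
    S_b, v_alv, V_L = mechanics_map(curves, tree, 0.0, P)
    S_a = S_b.copy()
    Vm = fill * S_b[:N_CONDUCTING] * tree.lengths[:N_CONDUCTING]
    cfg = cfg or StepperConfig()
    S_a[:N_CONDUCTING] = _floored_air_area(
        S_b[:N_CONDUCTING], Vm, tree.lengths[:N_CONDUCTING],
        cfg.r_a_floor_frac**2,
    )
    return LungState(
        t=0.0, S_a=S_a, S_b=S_b, v_alv=v_alv, P_air=P, V_L=V_L, Vm=Vm
    )


def run_simulation(
    maneuver: ManeuverSpec,
    fixture,
    cfg: StepperConfig | None = None,
    tree: TreeSpec | None = None,
    curves: PVCurves | None = None,
    fluids: FluidConstants | None = None,
    duration: float | None = None,
    record_stride: int = 1,
    initial_state: LungState | None = None,
) -> SimulationResult:
    """Integrate a full maneuver session from the rest state.

    Records traces every ``record_stride`` steps (the initial state is
    always recorded).  On a step failure the partial result is returned
    with ``completed=False``.
    """
    cfg = cfg or StepperConfig()
    tree = tree or build_tree_spec()
    curves = curves or build_pv_curves()
    fluids = fluids or FluidConstants()
    state = initial_state or find_rest_state(curves, tree, fixture, fluids, cfg)
    state0 = state.copy()
    stepper = _Stepper(tree, curves, fluids, cfg)

    duration = duration if duration is not None else maneuver.session.duration
    n_steps = int(round(duration / cfg.dt))

    # FRC-referenced baseline for the relative resistance trace
    S_b_rest = state0.S_b.copy()
    Vm0 = state0.mucus_volumes(tree)
    R0 = resistance_from_mucus(tree, S_b_rest, Vm0, fluids, cfg.r_a_floor_frac)

    rec: dict[str, list] = {k: [] for k in (
        "t", "P_ext", "V_L", "v_out", "phi_mouth", "iSh", "r", "R_inst",
        "mmp", "Vm")}

    def record(st: LungState, p_ext: float) -> None:
        Vm = st.mucus_volumes(tree)
        rec["t"].append(st.t)
        rec["P_ext"].append(p_ext)
        rec["V_L"].append(st.V_L)
        rec["v_out"].append(st.v_out)
        rec["phi_mouth"].append(st.phi_a[0])
        rec["iSh"].append(instantaneous_shrek(tree, st.phi_a, st.S_a, fluids))
        rec["r"].append(
            resistance_from_mucus(tree, S_b_rest, Vm, fluids, cfg.r_a_floor_frac)
            / R0
        )
        rec["R_inst"].append(tree_resistance(tree, st.S_a, fluids))
        rec["mmp"].append(_mmp(Vm, st.v_out))
        rec["Vm"].append(Vm)

    record(state, external_pressure(maneuver, 0.0))
    completed = True

    def p_of_t(t: float) -> float:
        return external_pressure(maneuver, t)

    try:
        for k in range(1, n_steps + 1):
            t_next = k * cfg.dt
            state = stepper.advance_adaptive(state, (k - 1) * cfg.dt, t_next, p_of_t)
            if k % record_stride == 0 or k == n_steps:
                record(state, p_of_t(t_next))
    except StepFailure:
        completed = False

    return SimulationResult(
        times=np.array(rec["t"]),
        P_ext=np.array(rec["P_ext"]),
        V_L=np.array(rec["V_L"]),
        v_out=np.array(rec["v_out"]),
        phi_mouth=np.array(rec["phi_mouth"]),
        iSh=np.array(rec["iSh"]),
        r=np.array(rec["r"]),
        R_inst=np.array(rec["R_inst"]),
        mmp=np.array(rec["mmp"]),
        mucus_volumes=np.array(rec["Vm"]),
        final_state=state,
        initial_state=state0,
        tree=tree,
        curves=curves,
        fluids=fluids,
        cfg=cfg,
        maneuver=maneuver,
        newton_iterations=stepper.newton_iterations,
        clamp_events=stepper.clamp_events,
        soft_accepts=stepper.soft_accepts,
        substep_events=stepper.substep_events,
        completed=completed,
    )


def _mmp(Vm: np.ndarray, v_out: float) -> float:
    z = np.arange(N_CONDUCTING)
    denom = v_out + float(np.sum(Vm))
    if denom <= 0:
        return np.nan
    return float((-v_out + np.sum(z * Vm)) / denom)
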