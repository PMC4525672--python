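"""Compiled residual kernel for the implicit stepper.

The quasi-Newton driver evaluates the step residual thousands of times
per simulated second; this module holds a numba-compiled twin of the
pure-numpy residual in :mod:`mucodyn.dynamics`, specialized to the
closed-form default pressure-volume curves.  The Python path remains
the reference implementation (and the only one available with
user-tabulated curves); both are asserted equivalent in the tests.

Constant packing
----------------
``pack_constants`` flattens the tree, curve, fluid and stepper
constants into plain float64 arrays so the kernel signature stays
stable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N = 23
NC = 17


def pack_constants(tree, curves, fluids, cfg, min_area_frac):
    """Flatten model constants for the kernel. Returns (tree_c, scal)."""
    p = curves.params
    tree_c = np.zeros((8, NC))
    tree_c[0] = tree.lengths[:NC]
    tree_c[1] = tree.alpha0
    tree_c[2] = tree.alpha0_prime
    tree_c[3] = tree.n2
    tree_c[4] = tree.A_m
    tree_c[5] = tree.P2
    tree_c[6] = tree.multiplicity[:NC]
    tree_c[7] = 0.0  # spare
    vols = curves.vols
    scal = np.array([
        vols.RV,                      # 0
        vols.TLC,                     # 1
        float(p["P_half"]),           # 2
        float(p["P_scale"]),          # 3
        float(p["tissue_amp"]),       # 4
        float(p["tissue_k"]),         # 5
        tree.alpha_duct,              # 6
        tree.generations[17].length,  # 7  L_ad
        float(tree.n_adu_total),      # 8
        fluids.mu_air,                # 9
        fluids.sigma0,                # 10
        fluids.mu_mucus,              # 11
        cfg.r_a_floor_frac**2,        # 12 floor area fraction
        min_area_frac,                # 13 buckling patency fraction
        1.0 if cfg.rigid_interface else 0.0,  # 14
        float(cfg.inner_max_iter),    # 15
        cfg.inner_tol,                # 16
        tree.lengths[NC],             # 17 acinar length (== L_ad)
    ])
    if cfg.mucus_mode != "implicit":
        scal[15] = 1.0  # semi-implicit: a single inner pass
    return tree_c, scal


@njit(cache=True, fastmath=False)
def _lambert(dP, alpha0, alpha0p, n2, Am, P2, minfrac):
    """Scalar pressure-area law with the C^1 compressive saturation."""
    if dP <= 0.0:
        f = minfrac * alpha0
        span = alpha0 - f
        return (f + span * np.exp(alpha0p * dP / span)) * Am
    return (1.0 - (1.0 - alpha0) * (1.0 - dP / P2) ** (-n2)) * Am


@njit(cache=True, fastmath=False)
def _lambert_deriv(dP, alpha0, alpha0p, n2, Am, P2, minfrac):
    if dP <= 0.0:
        f = minfrac * alpha0
        span = alpha0 - f
        return alpha0p * np.exp(alpha0p * dP / span) * Am
    return -(1.0 - alpha0) * (n2 / P2) * (1.0 - dP / P2) ** (-n2 - 1.0) * Am


@njit(cache=True, fastmath=False)
def _vtbt_zero_pair(V, tree_c, scal, minfrac):
    """(V_tbt, dV_tbt/dV) at zero airway pressure."""
    RV, TLC = scal[0], scal[1]
    x = (V - RV) / (TLC - RV)
    pt = scal[4] * np.expm1(scal[5] * x)
    dpt = scal[4] * scal[5] / (TLC - RV) * np.exp(scal[5] * x)
    v = 0.0
    dv = 0.0
    for z in range(NC):
        v += _lambert(pt, tree_c[1, z], tree_c[2, z], tree_c[3, z],
                      tree_c[4, z], tree_c[5, z], minfrac) * tree_c[0, z]
        dv += _lambert_deriv(pt, tree_c[1, z], tree_c[2, z], tree_c[3, z],
                             tree_c[4, z], tree_c[5, z], minfrac) * tree_c[0, z]
    return v, dv * dpt


@njit(cache=True, fastmath=False)
def residual_kernel(P, P_ext, prev_Sa, prev_valv, prev_Vm, V_guess, dt,
                    tree_c, scal):
    """One full residual evaluation.

    Returns (ok, res, S_b, S_a, v_alv, V_L, C, phi, phi_m, Vm, occl).
    ``ok`` is 0 on success, nonzero when the volume solve fails.
    """
    RV, TLC = scal[0], scal[1]
    p_half, p_scale = scal[2], scal[3]
    t_amp, t_k = scal[4], scal[5]
    alpha, L_ad, n_adu = scal[6], scal[7], scal[8]
    mu_a, sig, mu_m = scal[9], scal[10], scal[11]
    floor_area, minfrac = scal[12], scal[13]
    rigid = scal[14] > 0.5
    inner_max = int(scal[15])
    inner_tol0 = scal[16]
    span_v = TLC - RV

    res = np.zeros(N)
    S_b = np.zeros(N)
    S_a = np.zeros(N)
    v_alv = np.zeros(6)
    C = np.zeros(N)
    phi = np.zeros(N)
    phi_m = np.zeros(NC)
    Vm = prev_Vm.copy()

    # ---- acinar mechanics -------------------------------------------------
    V_ac = 0.0
    duct_sum = np.zeros(6)
    for j in range(6):
        z = NC + j
        x = P[z] - P_ext
        V_rs = RV + span_v / (1.0 + np.exp(-(x - p_half) / p_scale))
        vt, _ = _vtbt_zero_pair(V_rs, tree_c, scal, minfrac)
        v_adu = (V_rs - vt) / n_adu
        mult = 2.0**z
        duct_sum[j] = mult * alpha * v_adu / L_ad
        v_alv[j] = (1.0 - alpha) * v_adu / 58.0
        V_ac += mult * v_adu

    # ---- lung-volume fixed point (safeguarded Newton) ---------------------
    lo = RV + 1e-7
    hi = TLC - 1e-7
    # residual g(V) = V - V_ac - sum lambert(pt(V) - P[z]) l_z
    g_lo = 0.0
    g_hi = 0.0
    for pass_i in range(2):
        V = lo if pass_i == 0 else hi
        x = (V - RV) / span_v
        pt = t_amp * np.expm1(t_k * x)
        v = 0.0
        for z in range(NC):
            v += _lambert(pt - P[z], tree_c[1, z], tree_c[2, z], tree_c[3, z],
                          tree_c[4, z], tree_c[5, z], minfrac) * tree_c[0, z]
        if pass_i == 0:
            g_lo = V - V_ac - v
        else:
            g_hi = V - V_ac - v
    if (g_lo > 0 and g_hi > 0) or (g_lo < 0 and g_hi < 0):
        return (1, res, S_b, S_a, v_alv, 0.0, C, phi, phi_m, Vm, 0)
    if g_lo > 0.0:
        tmp = lo
        lo = hi
        hi = tmp
    V = V_guess
    if not (min(lo, hi) < V < max(lo, hi)):
        V = 0.5 * (lo + hi)
    V_L = -1.0
    for _ in range(60):
        x = (V - RV) / span_v
        pt = t_amp * np.expm1(t_k * x)
        dpt = t_amp * t_k / span_v * np.exp(t_k * x)
        v = 0.0
        dv = 0.0
        for z in range(NC):
            v += _lambert(pt - P[z], tree_c[1, z], tree_c[2, z],
                          tree_c[3, z], tree_c[4, z], tree_c[5, z],
                          minfrac) * tree_c[0, z]
            dv += _lambert_deriv(pt - P[z], tree_c[1, z], tree_c[2, z],
                                 tree_c[3, z], tree_c[4, z], tree_c[5, z],
                                 minfrac) * tree_c[0, z]
        g = V - V_ac - v
        dg = 1.0 - dv * dpt
        if abs(g) < 1e-9:
            V_L = V
            break
        if g < 0.0:
            lo = V
        else:
            hi = V
        if dg > 1e-12:
            V_new = V - g / dg
        else:
            V_new = 0.5 * (lo + hi)
        if not (min(lo, hi) < V_new < max(lo, hi)):
            V_new = 0.5 * (lo + hi)
        V = V_new
    if V_L < 0.0:
        return (2, res, S_b, S_a, v_alv, 0.0, C, phi, phi_m, Vm, 0)

    # ---- bronchus areas ----------------------------------------------------
    x = (V_L - RV) / span_v
    pt = t_amp * np.expm1(t_k * x)
    for z in range(NC):
        S_b[z] = _lambert(pt - P[z], tree_c[1, z], tree_c[2, z], tree_c[3, z],
                          tree_c[4, z], tree_c[5, z], minfrac)
    for j in range(6):
        S_b[NC + j] = duct_sum[j]

    # ---- mucus / flow inner loop ------------------------------------------
    phi_alv = np.zeros(6)
    for j in range(6):
        phi_alv[j] = -(v_alv[j] - prev_valv[j]) / dt
    vmmax = 0.0
    for z in range(NC):
        if prev_Vm[z] > vmmax:
            vmmax = prev_Vm[z]
    inner_tol = inner_tol0
    if 1e-9 * vmmax > inner_tol:
        inner_tol = 1e-9 * vmmax

    r_b = np.zeros(N)
    for z in range(N):
        mult = 2.0**z
        r_b[z] = np.sqrt(S_b[z] / mult / np.pi)

    avail = np.zeros(NC)
    for z in range(NC):
        avail[z] = prev_Vm[z] / (2.0**z * dt)

    dSdt = np.zeros(N)
    for j in range(6):
        dSdt[NC + j] = (S_b[NC + j] - prev_Sa[NC + j]) / dt

    r_a = np.zeros(N)
    inflow = np.zeros(NC)
    Vm_new = np.zeros(NC)
    for _inner in range(inner_max):
        # floored air areas and their rates
        for z in range(NC):
            raw = S_b[z] - Vm[z] / tree_c[0, z]
            lof = floor_area * S_b[z]
            w = 0.5 * lof
            sa = 0.5 * (raw + lof + np.sqrt((raw - lof) ** 2 + w * w))
            if sa > S_b[z]:
                sa = S_b[z]
            S_a[z] = sa
            dSdt[z] = (sa - prev_Sa[z]) / dt
            r_a[z] = np.sqrt(sa / (2.0**z) / np.pi)
        for j in range(6):
            r_a[NC + j] = r_b[NC + j]
        # leaf-to-root flows (up-tree positive)
        child = 0.0
        for z in range(N - 1, -1, -1):
            mult = 2.0**z
            own = -dSdt[z] / mult * tree_c[0, z] if z < NC else (
                -dSdt[z] / mult * L_ad
            )
            alv = 58.0 * phi_alv[z - NC] if z >= NC else 0.0
            phi[z] = own + 2.0 * child + alv
            child = phi[z]
        # gradients from the down-tree flux (-phi)
        for z in range(N):
            f = -phi[z]
            s = 0.0
            if f > 0.0:
                s = -1.0
            elif f < 0.0:
                s = 1.0
            fh = abs(f)
            ra = r_a[z]
            rb = r_b[z]
            poise = np.pi * ra**4 / (8.0 * mu_a)
            ch = fh / poise
            if (not rigid) and ra < rb * (1.0 - 1e-14):
                phi1 = 2.0 * sig / rb * poise
                phi2 = (np.pi * ra * sig * (rb - ra) ** 2 / (2.0 * mu_m)
                        + sig * np.pi * ra**3 / (4.0 * mu_a))
                if fh > phi1 and fh <= phi2:
                    A = (np.pi * ra**2 * rb**2 / (4.0 * mu_m)
                         + np.pi * ra**4 / (8.0 * mu_a))
                    B = -(np.pi * ra**2 * rb * sig / mu_m + fh)
                    Cc = np.pi * ra**2 * sig**2 / mu_m
                    disc = B * B - 4.0 * A * Cc
                    if disc < 0.0:
                        disc = 0.0
                    ch = (-B + np.sqrt(disc)) / (2.0 * A)
                elif fh > phi2:
                    K1 = (np.pi * ra**2 * (rb**2 - ra**2) / (4.0 * mu_m)
                          + np.pi * ra**4 / (8.0 * mu_a))
                    K0 = np.pi * ra**2 * sig * (rb - ra) / mu_m
                    ch = (fh + K0) / K1
            C[z] = s * ch
        # mucus fluxes in the conducting generations
        for z in range(NC):
            cc = C[z]
            if cc == 0.0:
                phi_m[z] = 0.0
                continue
            s = 1.0 if cc > 0 else -1.0
            chat = abs(cc)
            ra = r_a[z]
            rb = r_b[z]
            r0 = 2.0 * sig / chat
            if r0 >= rb:
                phi_m[z] = 0.0
                continue
            a = r0
            if a < ra:
                a = ra
            u_y = chat / (4.0 * mu_m) * (rb * rb - a * a) - sig / mu_m * (rb - a)
            if u_y < 0.0:
                u_y = 0.0
            q_sh = (chat * np.pi / (8.0 * mu_m) * (rb * rb - a * a) ** 2
                    - sig * np.pi / (3.0 * mu_m)
                    * (rb**3 - 3.0 * rb * a * a + 2.0 * a**3))
            if q_sh < 0.0:
                q_sh = 0.0
            phi_m[z] = -s * (u_y * np.pi * (a * a - ra * ra) + q_sh)
        if phi_m[NC - 1] > 0.0:
            phi_m[NC - 1] = 0.0  # mucus cannot enter the acini
        # C^1 saturation at the available-mucus limit
        for z in range(NC):
            phi_m[z] = phi_m[z] * avail[z] / (abs(phi_m[z]) + avail[z] + 1e-300)
        for z in range(NC):
            inflow[z] = 0.0
        for z in range(1, NC):
            if phi_m[z - 1] > 0.0:
                inflow[z] += 0.5 * phi_m[z - 1]
        for z in range(NC - 1):
            if phi_m[z + 1] < 0.0:
                inflow[z] += -2.0 * phi_m[z + 1]
        delta = 0.0
        for z in range(NC):
            vn = prev_Vm[z] + 2.0**z * (inflow[z] - abs(phi_m[z])) * dt
            if vn < 0.0:
                vn = 0.0
            d = abs(vn - Vm[z])
            if d > delta:
                delta = d
            Vm_new[z] = vn
        for z in range(NC):
            Vm[z] = Vm_new[z]
        if delta < inner_tol:
            break

    occl = 0
    for z in range(NC):
        raw = S_b[z] - Vm[z] / tree_c[0, z]
        lof = floor_area * S_b[z]
        w = 0.5 * lof
        sa = 0.5 * (raw + lof + np.sqrt((raw - lof) ** 2 + w * w))
        if sa > S_b[z]:
            sa = S_b[z]
        S_a[z] = sa
        if S_b[z] * tree_c[0, z] < Vm[z]:
            occl += 1
    for j in range(6):
        S_a[NC + j] = S_b[NC + j]

    # ---- implied mid-airway pressures --------------------------------------
    cum = 0.0
    for z in range(N):
        ll = tree_c[0, z] if z < NC else L_ad
        res[z] = P[z] - (cum + 0.5 * C[z] * ll)
        cum += C[z] * ll
    return (0, res, S_b, S_a, v_alv, V_L, C, phi, phi_m, Vm, occl)
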