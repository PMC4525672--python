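# Model and methods

## Scope and assumptions

`mucodyn` is a minimal, quasi-static model of how a homogeneous chest
pressure moves air and mucus in a human lung. The lung is an idealized
symmetric bifurcating tree of 23 generations; all airways of a
generation are identical, so the state reduces to per-generation
quantities (generation-summed lumen areas, one mid-airway pressure per
generation). Tissue mechanics is static: airway walls are always in
equilibrium with their transmural pressure, and the lung tissue
pressure depends on lung volume only. Air flow is incompressible,
fully developed, inertialess Stokes flow; mucus is a Bingham fluid in
an axisymmetric annulus of uniform thickness along each airway.
Excluded by construction: spatially inhomogeneous chest pressure,
asymmetric branching, turbulence and unsteady (Womersley) profiles,
mucociliary clearance, gravity and surface tension, hysteresis in any
constitutive law, and patient-specific calibration.

## Geometry

Generations 0–16 (conducting airways) carry per-generation lengths and
pressure–area constants from the packaged table
(`src/mucodyn/data/lambert_airways.csv`); the tabulated maximal areas
`A_m` are generation-summed (the per-airway area is `A_m/2^z`; a
per-airway reading of 180 cm² at generation 16 would be physically
impossible). Generations 17–22 are acinar alveolar ducts of length
`L_ad = 0.7 mm` carrying 58 alveoli each; an alveolar duct plus its
alveoli is an *alveolar duct unit* (2¹⁷·63 ≈ 8.26·10⁶ of them; a
constant fraction α = 0.17 of a unit's volume is duct lumen). Scaling
volumes: TLC 6.5 L, VC 5 L, RV 1.5 L, FRC = RV + 0.35·VC = 3.25 L.

## Wall mechanics

A conducting airway's generation-summed lumen area follows a sigmoid
in the transmural pressure ΔP = P_tissue(V_L) − P_air:

* distension (ΔP > 0): `S = (1 − (1−α₀)(1 − ΔP/P₂)^(−n₂)) A_m` with
  `P₂ = −n₂(1−α₀)/α₀′` — increasing and saturating at `A_m`;
* compression (ΔP ≤ 0): the tabulated compressive branch
  `α₀(1−ΔP/P₁)^(−n₁)A_m` (with `P₁ = α₀n₁/α₀′`) assigns peripheral
  generations collapse pressures of only a few pascals; taken
  literally, any expiratory effort pinches the model tree to ~10⁻³ of
  its lumen area, the network becomes numerically singular, and the
  quasi-static frame has no gas trapping or reopening physics to give
  that state meaning. The live mechanics therefore use a C¹
  exponential saturation matched to the sigmoid's value (`α₀A_m`) and
  slope (`α₀′A_m`) at ΔP = 0 and decaying to a residual patency of
  `MIN_AREA_FRAC·α₀A_m` (default 0.8): buckled airways retain most of
  their zero-pressure lumen. The scalar `lambert_area` API keeps the
  pure tabulated law for reference.

Both branches are C¹ at ΔP = 0 by construction.

Acinar units follow the static respiratory-system curve: a unit at
air pressure `P` under chest pressure `P_ext` has volume
`v_adu = [V_L,rs(P − P_ext) − V_tbt(V_L,rs(P − P_ext), 0)]/(2¹⁷·63)`,
where the inner conducting-tree volume is evaluated with atmospheric
pressure throughout (the configuration of the static measurements).
Duct area and per-alveolus volume split `v_adu` by the constant α.

The lung volume closes the system through the fixed point
`V_L = V_ac(P_air, P_ext) + V_tbt(V_L, P_air)`, solved by a
safeguarded Newton iteration (bisection backup, |residual| < 10⁻⁹ m³).
Under the default curves the conducting-tree volume grows with `V_L`
with slope well below one, so the root is unique (checked numerically
over the state space visited).

## Reconstructed static curves

The original static volume–pressure data exist only as plotted curves,
so the defaults are closed forms anchored at every printed quantity;
they are the package's main source of quantitative deviation, and both
are replaceable by user-supplied monotone tables (PCHIP-interpolated,
strict monotonicity validated).

* `V_L,rs(ΔP) = RV + (TLC−RV) / (1 + exp(−(ΔP − P_half)/P_scale))`,
  with the two parameters fixed exactly by `V(0) = FRC` and
  `V(+5 cmH₂O) = FRC + 0.5 L`, so quiet breathing at −5 cmH₂O produces
  the rest tidal volume by construction (rest compliance ≈ 0.095
  L/cmH₂O).
* `P_tissue(V) = A(exp(k·(V−RV)/(TLC−RV)) − 1)`, fixed by
  `P_tissue(FRC) = 500 Pa` (the stated FRC transmural pressure;
  config-exposed as `frc_transmural_pa`) and `P_tissue(TLC) = 30
  cmH₂O`.

The 500 Pa anchor deserves a note. The tabulated airway diameters are
mutually consistent with a transmural pressure of ≈50 Pa, not 500 Pa,
and anchoring at 50 Pa reproduces the printed FRC decomposition
(bronchial tree 0.67 L, alveoli 2.58 L) essentially exactly. But at
that operating point every strong compression drives mid-tree
transmural pressures negative, buckles the mucus-laden generations
onto their content, and makes the stepping problem orders of magnitude
stiffer (50–100 residual evaluations per step even with heavy
regularization). The default keeps the stated 500 Pa anchor, where the
model integrates robustly; its FRC decomposition (0.71 L / 2.54 L) is
within 6% of the printed values. The cost is that the airways sit near
the flat top of their sigmoids, so air shear on mucus is roughly half
of what the reference outcomes imply: the simulated quiet-breathing
Shrek number is ≈0.10 (reported ≈0.2), the final relative resistance
of a 230-s manual session at 20 cmH₂O is ≈0.94 (reported 0.79), and
the expulsion threshold is ≈20 cmH₂O (reported 16.5). These gaps are
reported as measured, not calibrated away.

## Two-phase hydrodynamics

For fully developed axisymmetric Stokes flow under axial gradient `C`,
the shear stress is `τ(r) = C·r/2` in both fluids. With yield radius
`r₀ = |2σ₀/C|` the mucus annulus `(r_a, r_b)` is solid for `r₀ ≥ r_b`
(air core is plain Poiseuille with no slip at `r_a`), carries a plug
attached to the interface for `r_a < r₀ < r_b`, and is fully yielded
for `r₀ ≤ r_a`. All fluxes integrate to closed forms; with `a =
clip(r₀, r_a, r_b)` and magnitudes (signs follow −C):

* plug/interface speed `u_y = (|C|/4μ_m)(r_b²−a²) − (σ₀/μ_m)(r_b−a)`,
* sheared-zone flux `(|C|π/8μ_m)(r_b²−a²)² −
  (σ₀π/3μ_m)(r_b³−3r_b a²+2a³)`,
* air flux `u_y π r_a² + |C| π r_a⁴/(8 μ_a)`.

Setting `r_a = 0` recovers the Buckingham–Reiner pipe flux, and the
forms agree with a test-only adaptive-quadrature integration of the
velocity profile to better than 10⁻⁷ relative over all regimes. The
inverse map (air flux → gradient), needed by the network solver, is
exact and piecewise closed-form: linear in the rigid-annulus and
fully-yielded regimes and the root of a quadratic in between (the plug
speed is `(|C|r_b−2σ₀)²/(4μ_m|C|)`). A `rigid_interface` option drops
the interface-velocity feedback on the air flux (with μ_m/μ_a ≈
5.6·10³ the coupling is a small correction); the coupled solution is
the default.

## Time stepping

One backward-Euler step advances the state under `P_ext(t+dt)`. The
unknown is the 23-vector of mid-airway pressures; each residual
evaluation runs mechanics (including the inner lung-volume solve),
backward differences for the area/volume rates, the leaf-to-root air
flow recursion `Φ_z = 2Φ_{z+1} − (dS_a/dt)·l_z − n_alv·dv_alv/dt`
(up-tree positive; at the root this telescopes to minus the rate of
change of total gas volume), the flux→gradient closure per
generation, the Bingham mucus fluxes with the directional
parent/daughter splitting (half of a downward parent flux, twice an
upward daughter flux, wrong-signed neighbours ignored; no mucus enters
the acini; trachea outflow accumulates into `v_out`), and finally the
implied pressures as cumulative gradient sums to mid-airway depth. In
the default fully-implicit mode the mucus cross-sections are iterated
to self-consistency inside the residual; a semi-implicit single-pass
mode is first-order equivalent and slightly cheaper.

Mucus volume per generation is carried as an explicit conserved state.
When a compressed wall shrinks toward its mucus content, the air lumen
is floored at `r_a ≥ 0.1·r_b` (C¹ blend) for the hydraulics and the
geometric identity `S_a = S_b − V_m/l` is relaxed rather than
destroying mucus mass; such occlusion events are counted and reported.
The available-mucus outflow limit and all floors are C¹ saturations:
hard clips put congested solutions exactly on kinks and defeat the
Newton iteration.

The nonlinear solver is a damped quasi-Newton method: a
finite-difference Jacobian factorized and reused across steps, kept
current with Broyden rank-one updates, refreshed whenever an iteration
makes poor progress, with a backtracking line search, a nonmonotone
rescue step at semismooth kinks, and adaptive step bisection on
failure. Tolerance is 10⁻⁴ Pa (max-norm) with a relative stagnation
acceptance of 5·10⁻³·|P|∞ for steps that reach the noise floor of the
inner fixed point; both acceptances are counted in the run summary.
The residual kernel has a numba-compiled twin, specialized to the
closed-form default curves and asserted equivalent to the numpy
reference in the tests; a full 230-s session (46 000 steps) runs in
~15 s on one core.

## Maneuver library

Quiet breathing is `P_v(1−cos(2πt/5))/2` with `P_v = −5 cmH₂O`
(0.2 Hz), always active and never ramped. Manual physiotherapy adds
`P_cp·max(sin(2πt/5), 0)` (a push on each expiration); HFCWO adds
`P_s + (P_o/2)·sin(2πft)`. Maneuver terms act on a 230-s session with
10-s lead-in/tail and 5-s linear ramps (the ramp shape is a choice;
only "progressive" application is specified). The manual term keeps
the global clock phase of the printed formula, with no per-breath
re-phasing. Focused-pulse devices are represented purely by their
equivalent pressures (piston pressure weighted by the piston-to-chest
area ratio).

## Initial mucus distribution

The default profile fills 10% of the bronchus lumen in generations
0–5, rises through 0.20 and 0.35 at generations 6–7 to a 50% peak at
generation 8, and decays geometrically (`0.5·e^(−λ(z−8))`,
λ = 0.3757084313795437) to zero at generation 16. The rise values and
the decay rate are frozen constants, calibrated once so that the mean
mucus position of the profile on the rest-state tree is 7.34, and not
recomputed at run time. The profile is immobile under quiet breathing
(air shear stays below σ₀ everywhere), which is the property that
motivated its shape.

## Outcome measures

* `v_out`: cumulative mucus volume expelled through the trachea.
* `r`: FRC-referenced relative resistance — the series/parallel
  air-core Poiseuille resistance of the conducting tree, evaluated
  with pressures reset to rest but the current mucus distribution,
  normalized by its pre-maneuver value (so r(0) = 1 exactly). An
  instantaneous-resistance trace is exported alongside.
* `mmp`: mucus-volume-weighted mean generation index; expelled volume
  enters the numerator with weight −1 (as if standing one generation
  above the trachea) — implemented as stated, flagged as a quirk.
* Shrek number: `iSh = (1/N)Σ 4μ_a|Φ_z|/(π r_z³ σ₀)` with N = 17
  conducting generations (config-overridable), per-airway flow
  magnitudes, and the current air-lumen radius (mucus thickening
  raises the local score); `Sh` is the trapezoidal time average. The
  resistance shortcut `R_aw|Φ_mouth|/(12Nσ₀)` (exact if every airway
  had length-to-diameter ratio 3) and a compliance-based estimate from
  `C_L·R_aw·|dP_ext/dt|` are exported as diagnostics.
* comfort number: `iCom = |(P_tissue(V_L) − P_tissue(V_L^vent)) /
  P_tissue(V_L^vent)|` against a quiet-breathing reference run on the
  same time grid; `Com` is its time average. Zero for quiet breathing
  by construction.

## Problem sizes used in the shipped checks

Quiet-breathing quantities use 25-s runs (five full breaths); the
manual-session resistance uses the full 230-s protocol; the expulsion
threshold is bracketed with 60-s sessions (10-s lead-in/tail, 40 s of
pushes — the threshold is decided within the first few pushes, and the
short session keeps the amplitude sweep inexpensive); the comparative
comfort checks use 60-s sessions.

## Known limitations

* The reconstructed static curves dominate the quantitative error
  budget (see above); all collapse-related behaviour beyond the
  saturated compressive branch is out of reach.
* Very high manual amplitudes (≈26 cmH₂O and above at the default
  operating point) drive mucus-congested states whose steps can fail
  to converge; runs then return partial results flagged
  `completed=False`.
* The wall law ignores the incompressibility of mucus: a wall may
  nominally shrink below its mucus content (occlusion events), during
  which the air lumen sits at its floor and the local geometry is
  approximate.
* Expelled-volume predictions near threshold are nanolitre-scale and
  sensitive to the tracheal shear margin; treat the threshold, not the
  expelled amount, as the robust quantity.
* Efficiency and comfort scores are model-internal screening numbers;
  they carry no clinical calibration.
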