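# Methods

This note documents the model behind `crtwork`: what is simulated, which
choices were genuinely open and how they were made, what the synthetic data
do and do not emulate, and the package's known limitations. Every number
quoted here is computed by the test suite or the examples; none is asserted
from outside the package.

## 1. Scope and reduction strategy

The package targets the *analysis* of regional myocardial work under
cardiac resynchronisation therapy — work rates, work modes, regional
aggregation, tension/strain-rate swaps, conservation checks and parameter
sensitivity — at desk scale. Full 3D electromechanics (finite-element
elasticity, monodomain ionic models, imaged fibre fields) is out of scope
and replaced by the smallest closures that preserve the analysed
quantities:

* only activation **times** feed the mechanics, so reaction–diffusion
  electrophysiology reduces to shortest-path travel times on the segment
  adjacency graph (an eikonal-style abstraction);
* the work formula uses only the fibre stress–strain-rate product, so 3D
  elasticity reduces to a three-wall thin-shell balance whose virtual-work
  structure is kept exact (§4).

## 2. Virtual patient

The generator emulates a dilated cardiomyopathy phenotype with severe
systolic dysfunction: LV EDV 280 mL, RV EDV 160 mL, LV wall 170 mL (30%
septal), RV free wall 45 mL, unloaded cavity volumes 150/90 mL, junction
radius 3.6 cm, sinus 69 bpm, pacing 100 bpm with AV delay 100 ms, QRS
target 154 ms, and a subendocardial scar occupying 35% of the most apical
septal segment. EDV/ESV and wall mass are not published for the phenotype's
source patient, so these are package defaults chosen from the dilated-HF
literature ranges (EDV 250–350 mL, LV mass 150–250 g, EF ≈ 25%); they are
**not** presented as any patient's values.

Layout: four circumferential columns (anterior, lateral, posterior,
septum) × four levels, four apical-cap segments (one per column) and a
four-level RV column facing the septum — 24 segments, the smallest count
that separates the four LV free-wall subregions plus septum and RV.
Segment areas and volumes carry ±5% seeded jitter; centroids sit on nested
idealised shells and are used only for inter-segment distances.

Synthetic measurements are forward simulations corrupted by configured
noise: a 500 Hz pressure wire (mmHg, Gaussian noise), endocardial
activation-time samples (Gaussian jitter), atrial-filling PV points from
quasi-static passive inflation, and the QRS duration as the activation
span. With all noise at zero the measurements equal the simulation exactly,
which is the basis of the recovery tests.

What the generator does **not** emulate: real catheter geometry, ectopy,
respiration or beat-to-beat variability, regional fibre architecture, MRI
segmentation error. A green recovery test therefore establishes that the
fitting machinery is correct and identifiable *within the model family*,
not that it would personalise a real heart.

## 3. Constitutive laws

Fibre stress is a scalar stand-in for the fibre component of the second
Piola–Kirchhoff stress, work-conjugate to the Green strain E
(λ = √(1+2E)); cross-fibre stresses are not modelled.

* **Active twitch** φ(t) = tanh²(t/τ_r)·tanh²((T−t)/τ_d) on [0, T], zero
  outside; σ_a0 = (1−scar)·T_peak·max(0, 1+β(λ−1))·φ(t−t_act).
* **Passive law** σ_p = k_eff·(e^{bE} − 1), k_eff = k·(1+(m−1)·scar).
* **Strain-rate closure** Ė = (σ_req − σ_p − σ_a0)/(η + a_v·σ_a0): a
  linear force–velocity correction on the active stress plus a parallel
  viscosity, inverted so the carried stress equals the wall-required
  stress.

Defaults (tunable; units internal kPa/mL/ms/cm):

| parameter | value | why |
|---|---|---|
| T_peak | 80 kPa | with the twitch ceiling ≈0.93 and activation dispersion, gives regional peak average tensions of 60–68 kPa and baseline EF ≈ 25% |
| τ_rise | 120 ms | tension must still be low while the early septal "flash" shortening happens; a fast rise makes the LBBB septum do spuriously large early work |
| τ_decay, T | 60, 340 ms | twitch tail inside the 400 ms window, so early-activated tissue relaxes while late tissue still pulls (the sinus septal negative-work tail) |
| β | 0.15 | weak length dependence; larger β makes the *peak* regional tension length-sensitive and breaks the observed near-invariance of peak tension under pacing (<2%) |
| a_v | 300 ms | caps free-shortening strain rates near the physiological 1e-3 ms⁻¹ scale |
| η | 800 kPa·ms | passive-tissue damping; sets quiescent relaxation time |
| k, b | 1.1 kPa, 8 | EDP ≈ 1.9 kPa at EDV 280 mL |
| m (scar stiffness) | 5 | not constrained by data; exposed in config and swept in the sensitivity scan |

These defaults were calibrated once, jointly, against the stated clinical
picture (EF 25±2%, <2% tension change under pacing, QRS 154 ms) and then
frozen; the calibration is part of the packaged reference patient, not a
per-run fit.

## 4. Mechanics closure and its energetics

LV free wall, septum and RV free wall are spherical caps over a shared
junction circle of radius y; cap heights are signed along the LV→RV axis
(septum bulges into the RV when P_LV > P_RV). Cavity volumes are signed
cap-volume differences. Within a wall, segments are series-coupled at a
common referential tension T_w = σ_i·h_ref,i — so an early-activated
segment shortens by stretching its neighbours at fixed cavity volume,
which is where negative work during IVC comes from.

Equilibrium is the stationarity of virtual work under the per-wall
area–strain compatibility constraints Σ_i a_i(1+2E_i) = π(x_w²+y²):

    Σ_w Γ_w ∇_q A_w = P_LV ∇_q V_LV + P_RV ∇_q V_RV,  T_w = 2Γ_w.

Two consequences, both verified by tests:

* The four q-equations imply the per-wall Laplace relations
  ΔP_w = T_w·c_w (c = 2x/(x²+y²)) and the **radial** junction balance
  exactly. The **axial** junction component is a constraint reaction —
  physically the valve-plane/basal anchoring the cap parametrisation
  cannot relax — and is reported by `shell_diagnostics` rather than driven
  to zero. Note the factor relative to the textbook thin-shell result
  (ΔP = 2σh/R): with a single fibre stress component conjugate to Green
  strain, the energy-consistent tension is σ·h_ref, not 2σh. Keeping the
  energy-consistent form is what makes the conservation check meaningful.
* Because equilibrium is variational, the discrete power balance
  Σ_i V_i σ_i Ė_i = P_LV V̇_LV + P_RV V̇_RV holds to O(Δq²) per step.
  `energy_balance` splits the carried stress into active work, stored
  passive energy (exact potential difference) and viscous dissipation and
  compares their sum with the boundary PV work; the default runs close the
  budget to ≈0.3% at dt = 1 ms, and the residual falls when dt is halved.

Time stepping: implicit Euler for strains and Windkessel states. Each step
solves a 9-unknown algebraic system (three wall tensions, four geometry
coordinates, two cavity pressures) with Powell's hybrid method, warm
started; per-segment strains are eliminated by an inner vectorised Newton
solve of the scalar implicit update. Scaled residual tolerance 1e-8.
Phases per cavity: IVC (volume fixed at EDV) → ejection (pressure matches
the three-element Windkessel load, flow from volume decrement) →
post-ejection (volume fixed) once flow would reverse. The end-diastolic
state is the passive-only equilibrium at prescribed EDVs, reached by a
short volume ramp; its pressures are the model's EDPs.

The Windkessel order is not constrained by the analysis; three-element
(R_c, R_p, C, with venous floor P_ven) is adopted per outflow. The
pulmonary P_ven is read as left-atrial pressure and set to 1.2 kPa
(≈9 mmHg, elevated as in heart failure); this also keeps the quiescent
heart's arterial run-off above the RV EDP, so a no-activation run stays
isovolumetric for the full window.

## 5. Activation stage

Edge travel time = distance/velocity with each half-edge at its endpoint
segment's local velocity; scar mixes in a slow phase linearly:
v_eff = v·(s·f + (1−f)) with s = 0.25 by default. LBBB is represented by
Purkinje-like seeds on the RV side only (mid/apical RV levels), so the LV
activates transseptally with the lateral wall last. CRT is the elementwise
minimum of the intrinsic map and a single LV-lateral epicardial seed map;
the intrinsic-to-paced offset defaults to 0 ms (fusion observed, relative
timing not published) and is configurable, as is the electrode segment.
Conduction velocity is calibrated by bisection (tolerance 0.1 ms, ≤100
iterations, geometric midpoint) against the QRS span; any positive span is
bracketable because travel times are 1/v-linear and map fusion discards
late seeds, so the only a-priori invalid target is a non-positive one.

## 6. Work analysis conventions

* Work rate uses the **active** stress only; passive work is stored
  elastically and accounted separately in the energy balance.
* "Peak" of a signed series is the extremum of largest magnitude, keeping
  its sign; percent change is the signed 100·(paced−sinus)/sinus (0→0
  maps to 0). An increase in the magnitude of a negative work value is
  therefore a positive percent change.
* Mode classification: σ_a < 0.1 kPa → non-working; else Ė ≤ ε →
  positive work; Ė > ε → negative work, with a stretch deadband
  ε = 2·10⁻⁵ ms⁻¹ (ties → positive). The deadband resolves an otherwise
  undefined tolerance question: solver-level stretch jitter in the default
  runs measures ≤1.6·10⁻⁵ ms⁻¹ while sustained physiological stretching
  is ≥6·10⁻⁵ ms⁻¹. Pass `eps_strain_rate=0` for the strict sign rule.
* Mode fractions weight the scar sub-volume of each segment as always
  non-working; the viable sub-volume follows the segment's mode. The
  partition is exact by construction (f_zero := 1 − f_pos − f_neg).
* The per-region IVC window is the adjacent cavity's IVC phase; the septum
  uses the LV window.
* With 4 segments per region, mode fractions are quantised in steps of
  roughly one segment volume; fraction *levels* are coarse even where the
  sinus/paced *ordering* is robust.

## 7. Calibration

Fit order mirrors clinical personalisation, each stage conditioned on the
previous: passive (k, b) against atrial-filling PV points by quasi-static
inflation least squares; Windkessel (R_c, R_p, C) against the
ejection-phase PV relation with the initial arterial pressure as a
nuisance parameter (a noise-free simulator trace is then matched exactly);
active (T_peak, τ_rise, τ_decay) by nested-simulation least squares on the
500 Hz pressure transient. Only three active parameters are fitted — a
single pressure transient cannot identify all seven, so β, a_v, η and the
twitch duration stay at defaults. Known identifiability limit: under 1%
pressure noise R_c and C recover to a few percent, but R_p (time constant
R_p·C ≈ 1.5 s, far longer than the ejection window) has a median error of
~20% from a single beat; the tests assert the measured bounds.

## 8. Sensitivity scan

One-at-a-time ±10% perturbations of the personalised parameter surface
(active, passive, scar, conduction, systemic afterload, EDV, wall volume)
plus a binary scar on/off toggle, all sharing one baseline run and its
calibrated conduction velocity; reported as percent change in the signed
peak regional average work rate. The factor list is this package's
reconstruction of the model's tunable surface and is not claimed to match
any published supplement.

## 9. Known limitations

* Desk-scale magnitudes: regional work densities here are ~2–3× the
  published patient-specific 3D values (the shell model concentrates all
  deformation in the fibre scalar); only directions and invariances are
  claimed, and the acceptance checks are framed accordingly.
* No frequency dependence (pacing rate is metadata), no filling phase or
  atrial kick beyond the ED state, no inertial blood dynamics, no
  cross-fibre or 3D wall stress, no long-term remodelling.
* The axial junction balance is carried by a modelled anchoring reaction
  (§4); geometries where that reaction would dominate (e.g. extreme
  single-cavity collapse) are outside the closure's validity.
* RV stroke volume is not constrained to match LV stroke volume over the
  simulated half cycle (no closed-loop circulation).
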