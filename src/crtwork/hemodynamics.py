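"""Coupled reduced-order biventricular mechanics.

Geometry.  Three mechanical walls — LV free wall, septum, RV free wall —
are spherical caps sharing a junction circle of radius ``y`` (the
valve-plane ring).  Cap heights ``x_w`` are signed along the LV→RV axis:
``x_LVFW < 0`` (bulging away from the RV), ``x_SEPT > 0`` when the septum
bulges into the RV (the usual case, P_LV > P_RV), ``x_RVFW > 0``.  Cavity
volumes are differences of signed cap volumes,
``V_LV = V_m(x_S) − V_m(x_L)``, ``V_RV = V_m(x_R) − V_m(x_S)``.

Within-wall heterogeneity.  Each wall is a series chain of segments at a
common referential membrane tension ``T_w = σ_i·h_ref,i`` (σ is the scalar
fibre second Piola–Kirchhoff stress, h_ref the reference thickness), so an
early-activated segment shortens by stretching its late neighbours at fixed
cavity volume — the source of negative work during isovolumetric
contraction.

Equilibrium.  The wall force balance is the stationarity condition of the
virtual-work functional under the per-wall area–strain compatibility
constraints ``π(x_w² + y²) = Σ_i a_i (1 + 2 E_i)``:

    Σ_w Γ_w ∇_q A_w(q) = P_LV ∇_q V_LV(q) + P_RV ∇_q V_RV(q),
    q = (x_L, x_S, x_R, y),    T_w = 2 Γ_w.

These four equations imply the per-wall Laplace relations
(``T_w c_w = ΔP_w`` with curvature ``c_w = 2 x_w/(x_w² + y²)``) and the
radial junction-ring balance exactly; the axial component is carried as a
valve-plane reaction (see docs/methods.md).  Because equilibrium is
variational, the discrete power balance
``Σ_i V_i σ_i Ė_i = P_LV V̇_LV + P_RV V̇_RV`` holds to time-discretisation
error, which is what makes the work-conservation analysis meaningful.

Phases.  Both cavities start in isovolumetric contraction (IVC, volume
held at EDV); a cavity switches to ejection when its pressure exceeds its
arterial load, ejects against a three-element Windkessel, and freezes its
volume again (post_ejection) when flow would reverse.  Time stepping is
implicit Euler with a Newton/Powell solve of the algebraic system each
step, from end diastole for 400 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import root

from . import constitutive as law
from .activation import ActivationMap, ConductionParams
from .constitutive import ActiveParams, PassiveParams
from .virtual_patient import VirtualPatient

__all__ = [
    "WindkesselParams",
    "ModelParams",
    "SimulationTrace",
    "PHASE_IVC",
    "PHASE_EJECTION",
    "PHASE_POST",
    "PHASE_NAMES",
    "cap_geometry",
    "windkessel_step",
    "run_simulation",
    "solve_static_state",
    "equilibrium_residual",
    "EquilibriumResiduals",
    "shell_diagnostics",
    "default_model_params",
]

PHASE_IVC, PHASE_EJECTION, PHASE_POST = 0, 1, 2
PHASE_NAMES = {PHASE_IVC: "IVC", PHASE_EJECTION: "ejection", PHASE_POST: "post_ejection"}

_WALL_ORDER = ("LV_free_wall", "septum", "RV_free_wall")


@dataclass(frozen=True)
class WindkesselParams:
    """Three-element Windkessel afterload (one instance per outflow)."""
    proximal_resistance: float      # R_c, kPa·ms/mL
    peripheral_resistance: float    # R_p, kPa·ms/mL
    compliance: float               # C, mL/kPa
    venous_pressure: float = 0.4    # kPa
    initial_pressure: float = 9.0   # kPa, arterial pressure at t = 0

    def __post_init__(self):
        if self.proximal_resistance <= 0 or self.peripheral_resistance <= 0 \
                or self.compliance <= 0:
            raise ValueError("Windkessel resistances and compliance must be > 0")
        if self.venous_pressure < 0:
            raise ValueError("venous pressure must be >= 0")

    def replace(self, **kw) -> "WindkesselParams":
        return replace(self, **kw)


def default_model_params() -> "ModelParams":
    return ModelParams(
        active=law.default_active_params(),
        passive=law.default_passive_params(),
        wk_sys=WindkesselParams(proximal_resistance=6.0, peripheral_resistance=135.0,
                                compliance=11.0, venous_pressure=0.4,
                                initial_pressure=9.5),
        # pulmonary distal pressure is the left-atrial pressure, elevated in
        # heart failure (~9 mmHg); it also keeps the quiescent heart's
        # arterial run-off from drifting below the RV end-diastolic pressure
        wk_pul=WindkesselParams(proximal_resistance=1.5, peripheral_resistance=20.0,
                                compliance=8.0, venous_pressure=1.2,
                                initial_pressure=2.0),
        conduction=ConductionParams(),
    )


@dataclass(frozen=True)
class ModelParams:
    active: ActiveParams
    passive: PassiveParams
    wk_sys: WindkesselParams
    wk_pul: WindkesselParams
    conduction: ConductionParams = field(default_factory=ConductionParams)

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class SimulationTrace:
    """Uniform-grid record of a simulated half cycle (end diastole → 400 ms)."""
    time: np.ndarray                # ms
    segment_ids: np.ndarray
    E: np.ndarray                   # (nt, nseg) Green strain
    Edot: np.ndarray                # (nt, nseg) ms⁻¹ (backward difference)
    sigma_a: np.ndarray             # (nt, nseg) kPa, isometric active stress
    sigma_p: np.ndarray             # (nt, nseg) kPa
    p_lv: np.ndarray                # kPa
    v_lv: np.ndarray                # mL
    phase_lv: np.ndarray            # int codes, PHASE_NAMES
    p_rv: np.ndarray
    v_rv: np.ndarray
    phase_rv: np.ndarray
    p_art_sys: np.ndarray           # kPa
    p_art_pul: np.ndarray
    q_sys: np.ndarray               # mL/ms, LV outflow
    q_pul: np.ndarray
    geometry: np.ndarray            # (nt, 4): x_L, x_S, x_R, y (cm)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def ejection_fraction_lv(self) -> float:
        return 100.0 * (self.v_lv[0] - self.v_lv.min()) / self.v_lv[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "time_ms": self.time,
            "p_lv_kpa": self.p_lv, "v_lv_ml": self.v_lv,
            "phase_lv": [PHASE_NAMES[p] for p in self.phase_lv],
            "p_rv_kpa": self.p_rv, "v_rv_ml": self.v_rv,
            "phase_rv": [PHASE_NAMES[p] for p in self.phase_rv],
            "p_art_sys_kpa": self.p_art_sys, "p_art_pul_kpa": self.p_art_pul,
        }
        for k, sid in enumerate(self.segment_ids):
            cols[f"E_{sid}"] = self.E[:, k]
        for k, sid in enumerate(self.segment_ids):
            cols[f"Edot_{sid}"] = self.Edot[:, k]
        for k, sid in enumerate(self.segment_ids):
            cols[f"sa_{sid}"] = self.sigma_a[:, k]
        for k, sid in enumerate(self.segment_ids):
            cols[f"sp_{sid}"] = self.sigma_p[:, k]
        return pd.DataFrame(cols)


# --------------------------------------------------------------------------
# elementary geometry / afterload operations

def cap_volume_signed(x, y):
    """Signed spherical-cap volume V = (π/6)·x·(x² + 3y²) (mL)."""
    return (math.pi / 6.0) * x * (x * x + 3.0 * y * y)


def cap_curvature(x, y):
    """Signed cap curvature c = 2x/(x² + y²) (cm⁻¹); 1/R for a hemisphere."""
    return 2.0 * x / (x * x + y * y)


def cap_geometry(midwall_area: float, junction_radius: float):
    """Solve the cap height from area and junction radius.

    Returns (cap height x ≥ 0, cap volume mL, curvature cm⁻¹) with
    A = π(x² + y²), V = (π/6)x(x² + 3y²), c = 2x/(x² + y²).
    """
    y = junction_radius
    x2 = midwall_area / math.pi - y * y
    if x2 < -1e-12 * max(1.0, y * y):
        raise ValueError(
            f"infeasible geometry: area {midwall_area:.6g} cm² < π·y² for y={y:.6g} cm")
    x = math.sqrt(max(x2, 0.0))
    return x, cap_volume_signed(x, y), cap_curvature(x, y)


def windkessel_step(p_art: float, q: float, dt: float, params: WindkesselParams) -> float:
    """Implicit-Euler update of the arterial (compliance) pressure:
    C·dP/dt = Q − (P − P_ven)/R_p."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rp, c = params.peripheral_resistance, params.compliance
    return (p_art + (dt / c) * (q + params.venous_pressure / rp)) / (1.0 + dt / (rp * c))


def windkessel_load_pressure(p_art_new: float, q: float, params: WindkesselParams) -> float:
    """Pressure the ventricle must match while ejecting flow Q."""
    return p_art_new + params.proximal_resistance * q


# --------------------------------------------------------------------------
# shell model internals

class _Shell:
    """Vectorised per-patient arrays and the per-step algebraic system."""

    def __init__(self, patient: VirtualPatient, params: ModelParams,
                 activation: ActivationMap | None, disable_active: bool):
        segs = sorted(patient.segments, key=lambda s: s.id)
        self.ids = np.array([s.id for s in segs])
        self.area = np.array([s.ref_midwall_area for s in segs])
        self.wall_volume = np.array([s.wall_volume for s in segs])
        self.h_ref = self.wall_volume / self.area
        self.scar = np.array([s.scar_fraction for s in segs])
        self.wall_code = np.array([_WALL_ORDER.index(s.wall) for s in segs])
        self.wall_masks = [self.wall_code == w for w in range(3)]
        self.wall_area = np.array([self.area[m].sum() for m in self.wall_masks])
        self.params = params
        self.disable_active = disable_active
        if activation is not None:
            amap = activation.as_dict()
            self.t_act = np.array([amap[int(i)] for i in self.ids])
        else:
            self.t_act = np.zeros_like(self.area)
        self.k_eff = params.passive.k_eff(self.scar)
        # residual scales
        self.s_area = self.wall_area
        self.s_q = 50.0 * 2.0 * math.pi * 4.0     # Γ·∂A/∂q scale, kPa·cm²
        self.s_vol = 100.0
        self.s_p = 5.0

    # -- constitutive helpers ---------------------------------------------
    def amplitude(self, t: float) -> np.ndarray:
        """(1−scar)·T_peak·φ(t − t_act): active amplitude before length factor."""
        if self.disable_active:
            return np.zeros_like(self.area)
        return (1.0 - self.scar) * self.params.active.t_peak_stress \
            * law.twitch(t - self.t_act, self.params.active)

    def sigma_a0(self, E: np.ndarray, amp: np.ndarray) -> np.ndarray:
        lam = np.sqrt(1.0 + 2.0 * E)
        return amp * np.maximum(0.0, 1.0 + self.params.active.beta * (lam - 1.0))

    def sigma_p(self, E: np.ndarray) -> np.ndarray:
        return self.k_eff * np.expm1(self.params.passive.b * E)

    # -- inner strain solves ----------------------------------------------
    def strains_static(self, gam: np.ndarray) -> np.ndarray:
        """Quiescent equilibrium strains: σ_p(E) = σ_req = 2Γ_w/h_ref."""
        sigma_req = 2.0 * gam[self.wall_code] / self.h_ref
        ratio = np.maximum(sigma_req / self.k_eff, -0.95)
        return np.log1p(ratio) / self.params.passive.b

    def strains_dynamic(self, gam: np.ndarray, e_prev: np.ndarray, t: float,
                        dt: float, amp: np.ndarray) -> np.ndarray:
        """Implicit-Euler strain update under the strain-rate closure
        Ė = (σ_req − σ_p − σ_a0)/(η + a_v σ_a0); scalar Newton per segment."""
        p = self.params.active
        sigma_req = 2.0 * gam[self.wall_code] / self.h_ref
        e = e_prev.copy()
        b = self.params.passive.b
        for _ in range(40):
            lam = np.sqrt(1.0 + 2.0 * np.maximum(e, -0.49))
            lf = 1.0 + p.beta * (lam - 1.0)
            act = lf > 0.0
            sa = amp * np.where(act, lf, 0.0)
            dsa = np.where(act, amp * p.beta / lam, 0.0)
            ebe = self.k_eff * np.exp(b * np.clip(e, -20.0, 20.0))
            sp = ebe - self.k_eff
            dsp = b * ebe
            den = p.eta + p.a_v * sa
            num = sigma_req - sp - sa
            g = e - e_prev - dt * num / den
            dg = 1.0 + dt * (dsp + dsa) / den + dt * num * p.a_v * dsa / den ** 2
            step = g / np.where(np.abs(dg) < 1e-12, 1e-12, dg)
            step = np.clip(step, -0.2, 0.2)
            e = np.maximum(e - step, -0.49)
            if np.max(np.abs(g)) < 1e-12:
                break
        return e

    # -- outer residual ----------------------------------------------------
    def residual(self, u: np.ndarray, ctx: dict) -> np.ndarray:
        gam = u[0:3]
        x = u[3:6]
        y = u[6]
        p_lv, p_rv = u[7], u[8]

        if ctx["mode"] == "static":
            e = self.strains_static(gam)
        else:
            e = self.strains_dynamic(gam, ctx["e_prev"], ctx["t"], ctx["dt"], ctx["amp"])

        res = np.empty(9)
        # area compatibility per wall
        for w in range(3):
            a_strain = np.sum(self.area[self.wall_masks[w]]
                              * (1.0 + 2.0 * e[self.wall_masks[w]]))
            res[w] = (math.pi * (x[w] ** 2 + y ** 2) - a_strain) / self.s_area[w]
        # variational equilibrium in q = (x_L, x_S, x_R, y)
        half_pi = 0.5 * math.pi
        res[3] = (gam[0] * 2.0 * math.pi * x[0]
                  + p_lv * half_pi * (x[0] ** 2 + y ** 2)) / self.s_q
        res[4] = (gam[1] * 2.0 * math.pi * x[1]
                  - (p_lv - p_rv) * half_pi * (x[1] ** 2 + y ** 2)) / self.s_q
        res[5] = (gam[2] * 2.0 * math.pi * x[2]
                  - p_rv * half_pi * (x[2] ** 2 + y ** 2)) / self.s_q
        res[6] = (np.sum(gam) * 2.0 * math.pi * y
                  - p_lv * math.pi * y * (x[1] - x[0])
                  - p_rv * math.pi * y * (x[2] - x[1])) / self.s_q
        # cavity closures
        v_lv = cap_volume_signed(x[1], y) - cap_volume_signed(x[0], y)
        v_rv = cap_volume_signed(x[2], y) - cap_volume_signed(x[1], y)
        for slot, (cav_phase, v_cav, p_cav, key) in enumerate(
                ((ctx["phase_lv"], v_lv, p_lv, "sys"),
                 (ctx["phase_rv"], v_rv, p_rv, "pul"))):
            if cav_phase == PHASE_EJECTION:
                wk = self.params.wk_sys if key == "sys" else self.params.wk_pul
                q = (ctx[f"v_prev_{key}"] - v_cav) / ctx["dt"]
                pa_new = windkessel_step(ctx[f"pa_{key}"], q, ctx["dt"], wk)
                res[7 + slot] = (p_cav - windkessel_load_pressure(pa_new, q, wk)) / self.s_p
            else:
                res[7 + slot] = (v_cav - ctx[f"v_target_{key}"]) / self.s_vol
        return res

    def solve(self, u0: np.ndarray, ctx: dict) -> np.ndarray:
        sol = root(self.residual, u0, args=(ctx,), method="hybr",
                   options={"xtol": 1e-13, "maxfev": 4000})
        r = self.residual(sol.x, ctx)
        if np.max(np.abs(r)) > 1e-8:
            raise RuntimeError(
                f"shell equilibrium solve failed at t={ctx.get('t', 'static')} "
                f"(phase LV={ctx['phase_lv']}, RV={ctx['phase_rv']}): "
                f"max scaled residual {np.max(np.abs(r)):.3e}")
        return sol.x

    def strains_for(self, u: np.ndarray, ctx: dict) -> np.ndarray:
        gam = u[0:3]
        if ctx["mode"] == "static":
            return self.strains_static(gam)
        return self.strains_dynamic(gam, ctx["e_prev"], ctx["t"], ctx["dt"], ctx["amp"])


def _volumes_from_u(u):
    x, y = u[3:6], u[6]
    v_lv = cap_volume_signed(x[1], y) - cap_volume_signed(x[0], y)
    v_rv = cap_volume_signed(x[2], y) - cap_volume_signed(x[1], y)
    return v_lv, v_rv


def _static_guess(shell: _Shell, patient: VirtualPatient, v_lv: float, v_rv: float):
    """Similarity-scaled initial guess for the static solve."""
    x_l0, x_s0, x_r0 = patient.unloaded_cap_heights_cm
    y0 = patient.junction_radius_cm
    v0_lv = cap_volume_signed(x_s0, y0) - cap_volume_signed(x_l0, y0)
    s = (v_lv / v0_lv) ** (1.0 / 3.0)
    x = np.array([x_l0 * s, x_s0 * s, x_r0 * s])
    y = y0 * s
    e0 = 0.5 * (s * s - 1.0)
    sp = shell.k_eff * np.expm1(shell.params.passive.b * e0)
    gam = np.array([np.mean(sp[m] * shell.h_ref[m]) / 2.0 for m in shell.wall_masks])
    gam = np.maximum(gam, 1e-3)
    p_lv = -2.0 * gam[0] * cap_curvature(x[0], y)
    p_rv = 2.0 * gam[2] * cap_curvature(x[2], y)
    return np.concatenate([gam, x, [y, max(p_lv, 1e-3), max(p_rv, 1e-3)]])


def solve_static_state(patient: VirtualPatient, params: ModelParams,
                       v_lv: float, v_rv: float, n_ramp: int = 6):
    """Quiescent (passive-only) equilibrium at prescribed cavity volumes.

    Returns (u, strains): the shell unknowns and per-segment Green strains.
    Used for end-diastolic initialisation and quasi-static passive inflation.
    """
    shell = _Shell(patient, params, activation=None, disable_active=True)
    u = _static_guess(shell, patient, v_lv, v_rv)
    v_lv0, v_rv0 = _volumes_from_u(u)
    for k in range(1, n_ramp + 1):
        frac = k / n_ramp
        ctx = {"mode": "static",
               "phase_lv": PHASE_IVC, "phase_rv": PHASE_IVC,
               "v_target_sys": v_lv0 + frac * (v_lv - v_lv0),
               "v_target_pul": v_rv0 + frac * (v_rv - v_rv0)}
        u = shell.solve(u, ctx)
    e = shell.strains_static(u[0:3])
    return u, e


def run_simulation(patient: VirtualPatient, activation: ActivationMap | None,
                   params: ModelParams, dt: float = 1.0, duration: float = 400.0,
                   disable_active: bool = False) -> SimulationTrace:
    """Simulate from end diastole for ``duration`` ms (default 400 ms).

    Starts with both cavities isovolumetric at their EDVs and strains in
    passive equilibrium; activation gates the active twitch per segment.
    ``disable_active`` forces σ_a ≡ 0 (quiescent-heart runs).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if activation is None and not disable_active:
        raise ValueError("an activation map is required unless disable_active=True")

    shell = _Shell(patient, params, activation, disable_active)
    u, e = solve_static_state(patient, params, patient.lv_edv, patient.rv_edv)

    n_steps = int(round(duration / dt))
    nt, ns = n_steps + 1, len(shell.ids)
    tr = SimulationTrace(
        time=np.arange(nt) * dt, segment_ids=shell.ids,
        E=np.zeros((nt, ns)), Edot=np.zeros((nt, ns)),
        sigma_a=np.zeros((nt, ns)), sigma_p=np.zeros((nt, ns)),
        p_lv=np.zeros(nt), v_lv=np.zeros(nt),
        phase_lv=np.zeros(nt, dtype=np.int8),
        p_rv=np.zeros(nt), v_rv=np.zeros(nt),
        phase_rv=np.zeros(nt, dtype=np.int8),
        p_art_sys=np.zeros(nt), p_art_pul=np.zeros(nt),
        q_sys=np.zeros(nt), q_pul=np.zeros(nt),
        geometry=np.zeros((nt, 4)))

    v_lv, v_rv = _volumes_from_u(u)
    pa = {"sys": params.wk_sys.initial_pressure, "pul": params.wk_pul.initial_pressure}
    phase = {"sys": PHASE_IVC, "pul": PHASE_IVC}
    v_target = {"sys": v_lv, "pul": v_rv}
    v_prev = {"sys": v_lv, "pul": v_rv}
    wk = {"sys": params.wk_sys, "pul": params.wk_pul}

    def record(k, u, e, e_prev, t, dt_step, q):
        amp = shell.amplitude(t)
        tr.E[k] = e
        tr.Edot[k] = (e - e_prev) / dt_step if dt_step else 0.0
        tr.sigma_a[k] = shell.sigma_a0(e, amp)
        tr.sigma_p[k] = shell.sigma_p(e)
        tr.p_lv[k], tr.p_rv[k] = u[7], u[8]
        tr.v_lv[k], tr.v_rv[k] = _volumes_from_u(u)
        tr.phase_lv[k], tr.phase_rv[k] = phase["sys"], phase["pul"]
        tr.p_art_sys[k], tr.p_art_pul[k] = pa["sys"], pa["pul"]
        tr.q_sys[k], tr.q_pul[k] = q["sys"], q["pul"]
        tr.geometry[k] = u[3:7]

    record(0, u, e, e, 0.0, 0.0, {"sys": 0.0, "pul": 0.0})

    for k in range(1, nt):
        t = k * dt
        amp = shell.amplitude(t)

        def make_ctx():
            return {"mode": "dynamic", "t": t, "dt": dt, "e_prev": e, "amp": amp,
                    "phase_lv": phase["sys"], "phase_rv": phase["pul"],
                    "v_target_sys": v_target["sys"], "v_target_pul": v_target["pul"],
                    "v_prev_sys": v_prev["sys"], "v_prev_pul": v_prev["pul"],
                    "pa_sys": pa["sys"], "pa_pul": pa["pul"]}

        ctx = make_ctx()
        u_new = shell.solve(u, ctx)

        # ejection ends when flow would reverse: redo the step holding volume
        redo = False
        vols = dict(zip(("sys", "pul"), _volumes_from_u(u_new)))
        for key in ("sys", "pul"):
            if phase[key] == PHASE_EJECTION:
                q_k = (v_prev[key] - vols[key]) / dt
                if q_k < 0.0:
                    phase[key] = PHASE_POST
                    v_target[key] = v_prev[key]
                    redo = True
        if redo:
            ctx = make_ctx()
            u_new = shell.solve(u, ctx)
            vols = dict(zip(("sys", "pul"), _volumes_from_u(u_new)))

        e_new = shell.strains_for(u_new, ctx)

        # arterial pressures and flows for this step
        q = {}
        for key in ("sys", "pul"):
            if phase[key] == PHASE_EJECTION:
                q[key] = (v_prev[key] - vols[key]) / dt
            else:
                q[key] = 0.0
            pa[key] = windkessel_step(pa[key], q[key], dt, wk[key])

        e_prev_step = e
        u, e = u_new, e_new
        record(k, u, e, e_prev_step, t, dt, q)

        # IVC → ejection when cavity pressure exceeds the arterial load
        p_cav = {"sys": u[7], "pul": u[8]}
        for key in ("sys", "pul"):
            if phase[key] == PHASE_IVC and p_cav[key] > pa[key]:
                phase[key] = PHASE_EJECTION
            v_prev[key] = vols[key]

    return tr


# --------------------------------------------------------------------------
# diagnostics

@dataclass(frozen=True)
class EquilibriumResiduals:
    """Named force-balance residuals of a shell state.

    ``laplace`` (kPa, per wall), ``junction_radial`` (kPa·cm) and the
    ``area``/``volume`` compatibility residuals vanish at solver-converged
    states.  ``junction_axial`` (kPa·cm) is the valve-plane reaction force
    per unit ring length and is generally nonzero (reported, not zeroed).
    """
    laplace: np.ndarray          # (3,) kPa: LVFW, septum, RVFW
    junction_axial: float        # kPa·cm
    junction_radial: float       # kPa·cm
    area: np.ndarray             # (3,) cm²
    volume: np.ndarray           # (2,) mL vs. targets

    def max_equilibrium_residual(self) -> float:
        """Largest residual among those the closure drives to zero (scaled)."""
        return max(np.max(np.abs(self.laplace)) / 5.0,
                   abs(self.junction_radial) / 200.0,
                   np.max(np.abs(self.area)) / 100.0,
                   np.max(np.abs(self.volume)) / 100.0)


def equilibrium_residual(unknowns, strains, sigma, patient: VirtualPatient,
                         v_targets) -> EquilibriumResiduals:
    """Force-balance residuals at a shell state.

    Parameters
    ----------
    unknowns : (x_LVFW, x_SEPT, x_RVFW, y, P_LV, P_RV)
    strains : per-segment Green strains (sorted by segment id)
    sigma : per-segment carried fibre stress σ (kPa), i.e. σ_p + σ_a0 plus
        rate terms; within a wall σ_i·h_ref,i is the common referential
        membrane tension at equilibrium
    v_targets : (V_LV, V_RV) phase-constraint volumes (mL)
    """
    x = np.asarray(unknowns[0:3], dtype=float)
    y, p_lv, p_rv = float(unknowns[3]), float(unknowns[4]), float(unknowns[5])
    segs = sorted(patient.segments, key=lambda s: s.id)
    area = np.array([s.ref_midwall_area for s in segs])
    h_ref = np.array([s.wall_volume / s.ref_midwall_area for s in segs])
    wall_code = np.array([_WALL_ORDER.index(s.wall) for s in segs])
    strains = np.asarray(strains, dtype=float)
    sigma = np.asarray(sigma, dtype=float)

    tension = np.empty(3)
    area_res = np.empty(3)
    for w in range(3):
        m = wall_code == w
        tension[w] = np.sum(sigma[m] * h_ref[m] * area[m]) / np.sum(area[m])
        area_res[w] = math.pi * (x[w] ** 2 + y ** 2) \
            - np.sum(area[m] * (1.0 + 2.0 * strains[m]))

    c = np.array([cap_curvature(xi, y) for xi in x])
    laplace = np.array([
        -tension[0] * c[0] - p_lv,                # LVFW: bulges away from RV
        tension[1] * c[1] - (p_lv - p_rv),        # septum
        tension[2] * c[2] - p_rv,                 # RVFW
    ])
    denom = x ** 2 + y ** 2
    junction_axial = float(np.sum(tension * 2.0 * x * y / denom))
    junction_radial = float(np.sum(tension * (y ** 2 - x ** 2) / denom))
    v_lv = cap_volume_signed(x[1], y) - cap_volume_signed(x[0], y)
    v_rv = cap_volume_signed(x[2], y) - cap_volume_signed(x[1], y)
    volume = np.array([v_lv - v_targets[0], v_rv - v_targets[1]])
    return EquilibriumResiduals(laplace=laplace, junction_axial=junction_axial,
                                junction_radial=junction_radial,
                                area=area_res, volume=volume)


def shell_diagnostics(trace: SimulationTrace, patient: VirtualPatient,
                      params: ModelParams, step: int) -> EquilibriumResiduals:
    """Equilibrium residuals at a recorded step of a simulation trace."""
    sigma = (trace.sigma_p[step] + trace.sigma_a[step]
             + (params.active.eta + params.active.a_v * trace.sigma_a[step])
             * trace.Edot[step])
    x_l, x_s, x_r, y = trace.geometry[step]
    unknowns = (x_l, x_s, x_r, y, trace.p_lv[step], trace.p_rv[step])
    return equilibrium_residual(unknowns, trace.E[step], sigma, patient,
                                (trace.v_lv[step], trace.v_rv[step]))
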