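"""Personalisation fits, mirroring the clinical calibration order.

Three stages, each conditioned on the previous:

1. ``fit_passive`` — the exponential passive law (k, b) from atrial-filling
   pressure–volume points, when the myocardium is quiescent (σ_a ≡ 0 and
   each point is a quasi-static equilibrium).
2. ``fit_windkessel`` — the three-element afterload (R_c, R_p, C) from the
   ejection-phase pressure–volume relation.
3. ``fit_active`` — the twitch amplitude and time scales
   (T_peak, τ_rise, τ_decay) by nested-simulation least squares on the
   500 Hz LV pressure transient.

No clinical parameter values exist to recover, so parameter recovery on
noise-free synthetic measurements is the testable surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .activation import ActivationMap
from .constitutive import PassiveParams
from .hemodynamics import (ModelParams, WindkesselParams, run_simulation,
                           solve_static_state, windkessel_step)
from .virtual_patient import VirtualPatient

__all__ = ["FitResult", "IdentifiabilityError", "passive_inflation_curve",
           "fit_passive", "fit_windkessel", "fit_active"]

log = logging.getLogger(__name__)


class IdentifiabilityError(ValueError):
    """Raised when the supplied data cannot constrain the fit."""


@dataclass(frozen=True)
class FitResult:
    parameters: object
    objective_value: float      # sum of squared residuals, fitted units²
    n_iterations: int
    converged: bool


def _result(ls_result, parameters) -> FitResult:
    return FitResult(parameters=parameters,
                     objective_value=float(2.0 * ls_result.cost),
                     n_iterations=int(ls_result.nfev),
                     converged=bool(ls_result.success))


def passive_inflation_curve(patient: VirtualPatient, params: ModelParams,
                            lv_volumes, rv_volumes=None) -> np.ndarray:
    """Quasi-static passive LV pressure (kPa) at prescribed LV volumes.

    The RV co-inflates proportionally to its EDV unless given explicitly.
    """
    lv_volumes = np.asarray(lv_volumes, dtype=float)
    if rv_volumes is None:
        rv_volumes = patient.rv_edv * lv_volumes / patient.lv_edv
    out = np.empty_like(lv_volumes)
    for i, (vl, vr) in enumerate(zip(lv_volumes, np.asarray(rv_volumes))):
        u, _ = solve_static_state(patient, params, vl, vr)
        out[i] = u[7]
    return out


def fit_passive(pv_points, patient: VirtualPatient, params: ModelParams,
                x0=(2.0, 6.0), bounds=((0.05, 1.0), (30.0, 30.0))) -> FitResult:
    """Least-squares fit of the passive stiffness scale k and exponent b to
    atrial-filling (pressure kPa, volume mL) points.

    The scar stiffness multiplier is held fixed.  Needs at least three
    points spanning a volume range.
    """
    pv = [(float(p), float(v)) for p, v in pv_points]
    if len(pv) < 3:
        raise IdentifiabilityError("need at least 3 PV points to fit (k, b)")
    pressures = np.array([p for p, _ in pv])
    volumes = np.array([v for _, v in pv])
    if np.ptp(volumes) <= 0:
        raise IdentifiabilityError("PV points must span a volume range")

    m_fixed = params.passive.scar_stiffness_multiplier

    def residuals(theta):
        k, b = theta
        trial = params.replace(passive=PassiveParams(
            k=k, b=b, scar_stiffness_multiplier=m_fixed))
        return passive_inflation_curve(patient, trial, volumes) - pressures

    res = least_squares(residuals, x0=x0, bounds=bounds, x_scale=(1.0, 5.0),
                        xtol=1e-10, ftol=1e-12)
    fitted = PassiveParams(k=float(res.x[0]), b=float(res.x[1]),
                           scar_stiffness_multiplier=m_fixed)
    log.info("fit_passive: k=%.4g b=%.4g objective=%.3e nfev=%d",
             fitted.k, fitted.b, 2.0 * res.cost, res.nfev)
    return _result(res, fitted)


def fit_windkessel(time_ms, pressure_kpa, volume_ml,
                   venous_pressure: float = 0.4,
                   x0=(3.0, 80.0, 15.0),
                   bounds=((0.1, 5.0, 0.5), (50.0, 1000.0, 200.0))) -> FitResult:
    """Fit (R_c, R_p, C) to an ejection-phase pressure–volume trace.

    Flow is the backward difference Q = −ΔV/Δt; the predicted ventricular
    pressure is the Windkessel load pressure P_art + R_c·Q with P_art
    integrated implicitly from the observed flow.  The arterial pressure at
    the first sample is an additional nuisance parameter, so a noise-free
    trace produced by the simulator is matched exactly.
    """
    t = np.asarray(time_ms, dtype=float)
    p = np.asarray(pressure_kpa, dtype=float)
    v = np.asarray(volume_ml, dtype=float)
    if len(t) < 4:
        raise IdentifiabilityError("ejection trace too short to fit (R_c, R_p, C)")
    dt = np.diff(t)
    q = -np.diff(v) / dt               # flow at samples 1..n-1
    if np.max(np.abs(q)) < 1e-9:
        raise IdentifiabilityError("no ejection flow in the supplied trace")

    def residuals(theta):
        rc, rp, c, pa0 = theta
        wk = WindkesselParams(proximal_resistance=rc, peripheral_resistance=rp,
                              compliance=c, venous_pressure=venous_pressure)
        pa = pa0
        pred = np.empty(len(p) - 1)
        for k in range(len(q)):
            pa = windkessel_step(pa, q[k], dt[k], wk)
            pred[k] = pa + rc * q[k]
        return pred - p[1:]

    x0 = tuple(x0) + (float(p[0]),)
    bounds = (tuple(bounds[0]) + (0.0,), tuple(bounds[1]) + (50.0,))
    res = least_squares(residuals, x0=x0, bounds=bounds,
                        x_scale=(1.0, 30.0, 5.0, 5.0), xtol=1e-14, ftol=1e-14)
    fitted = WindkesselParams(proximal_resistance=float(res.x[0]),
                              peripheral_resistance=float(res.x[1]),
                              compliance=float(res.x[2]),
                              venous_pressure=venous_pressure,
                              initial_pressure=float(res.x[3]))
    log.info("fit_windkessel: Rc=%.4g Rp=%.4g C=%.4g objective=%.3e nfev=%d",
             fitted.proximal_resistance, fitted.peripheral_resistance,
             fitted.compliance, 2.0 * res.cost, res.nfev)
    return _result(res, fitted)


def fit_active(time_ms, pressure_kpa, patient: VirtualPatient,
               params: ModelParams, activation: ActivationMap,
               x0=(50.0, 90.0, 50.0),
               bounds=((0.5, 20.0, 10.0), (250.0, 300.0, 200.0)),
               dt: float = 1.0, max_nfev: int = 60) -> FitResult:
    """Nested-simulation least squares for (T_peak, τ_rise, τ_decay).

    Passive and Windkessel parameters (and everything else in ``params``)
    are held fixed; each objective evaluation is a full forward simulation
    whose LV pressure is interpolated onto the measurement grid.
    Simulator failures propagate with the trial parameter values attached.
    """
    t = np.asarray(time_ms, dtype=float)
    p = np.asarray(pressure_kpa, dtype=float)
    duration = float(t[-1])

    def residuals(theta):
        tp, taur, taud = theta
        trial = params.replace(active=params.active.replace(
            t_peak_stress=tp, tau_rise=taur, tau_decay=taud))
        try:
            tr = run_simulation(patient, activation, trial, dt=dt,
                                duration=duration)
        except Exception as exc:
            raise RuntimeError(
                f"simulation failed during fit_active at T_peak={tp:.4g}, "
                f"tau_rise={taur:.4g}, tau_decay={taud:.4g}: {exc}") from exc
        return np.interp(t, tr.time, tr.p_lv) - p

    res = least_squares(residuals, x0=x0, bounds=bounds, diff_step=0.03,
                        x_scale=(50.0, 50.0, 50.0), xtol=1e-8, ftol=1e-8,
                        max_nfev=max_nfev)
    fitted = params.active.replace(t_peak_stress=float(res.x[0]),
                                   tau_rise=float(res.x[1]),
                                   tau_decay=float(res.x[2]))
    log.info("fit_active: T_peak=%.4g tau_rise=%.4g tau_decay=%.4g "
             "objective=%.3e nfev=%d", fitted.t_peak_stress, fitted.tau_rise,
             fitted.tau_decay, 2.0 * res.cost, res.nfev)
    return _result(res, fitted)
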