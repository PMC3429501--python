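"""Per-segment fibre-level material laws.

The fibre stress here is a scalar stand-in for the fibre component of the
second Piola–Kirchhoff stress, work-conjugate to the Green strain E
(stretch λ = sqrt(1 + 2E)).  Three ingredients close the reduced-order
mechanics:

* an activation-gated active twitch ``σ_a0`` (isometric active stress),
* an exponential passive law ``σ_p``,
* a strain-rate evolution law combining a linear force–velocity correction
  on the active stress with a parallel viscosity, so that the total carried
  stress is ``σ = σ_p + σ_a0 + (η + a_v·σ_a0)·Ė``.

Scar enters twice: full scar generates no active tension and scarred tissue
is stiffer by a configurable multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ActiveParams",
    "PassiveParams",
    "twitch",
    "active_stress_isometric",
    "passive_stress",
    "passive_stress_derivative",
    "passive_energy",
    "strain_rate_law",
    "default_active_params",
    "default_passive_params",
]


@dataclass(frozen=True)
class ActiveParams:
    """Active-twitch parameters.

    t_peak_stress : kPa, isometric peak active stress at λ = 1
    tau_rise, tau_decay : ms, rise/decay time scales of the twitch window
    twitch_duration : ms, total duration of the active window
    beta : dimensionless slope of the linear length dependence
    a_v : ms, force–velocity coefficient (viscous-like, scales with σ_a0)
    eta : kPa·ms, parallel viscosity
    """

    t_peak_stress: float = 80.0
    tau_rise: float = 120.0
    tau_decay: float = 60.0
    twitch_duration: float = 340.0
    beta: float = 0.15
    a_v: float = 300.0
    eta: float = 800.0

    def validate(self) -> None:
        for name in ("t_peak_stress", "tau_rise", "tau_decay",
                     "twitch_duration", "a_v", "eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ActiveParams.{name} must be > 0")
        if self.beta < 0:
            raise ValueError("ActiveParams.beta must be >= 0")

    def replace(self, **kw) -> "ActiveParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PassiveParams:
    """Exponential passive law σ_p = k_eff·(exp(bE) − 1).

    k : kPa, stiffness scale of healthy myocardium
    b : dimensionless exponent
    scar_stiffness_multiplier : ≥ 1, stiffness scale-up of full scar;
        mixed segments interpolate linearly in scar fraction.
    """

    k: float = 1.1
    b: float = 8.0
    scar_stiffness_multiplier: float = 5.0

    def validate(self) -> None:
        if self.k <= 0:
            raise ValueError("PassiveParams.k must be > 0")
        if self.b <= 0:
            raise ValueError("PassiveParams.b must be > 0")
        if self.scar_stiffness_multiplier < 1:
            raise ValueError("PassiveParams.scar_stiffness_multiplier must be >= 1")

    def k_eff(self, scar_fraction):
        return self.k * (1.0 + (self.scar_stiffness_multiplier - 1.0) * np.asarray(scar_fraction))

    def replace(self, **kw) -> "PassiveParams":
        return replace(self, **kw)


def default_active_params() -> ActiveParams:
    return ActiveParams()


def default_passive_params() -> PassiveParams:
    return PassiveParams()


def twitch(t_rel, params: ActiveParams):
    """Normalised activation twitch φ(t) ∈ [0, 1].

    φ(t) = tanh²(t/τ_rise) · tanh²((T − t)/τ_decay) inside the active window
    [0, twitch_duration], zero outside; continuous everywhere.
    """
    t = np.asarray(t_rel, dtype=float)
    inside = (t > 0.0) & (t < params.twitch_duration)
    ts = np.where(inside, t, 0.5 * params.twitch_duration)
    phi = (np.tanh(ts / params.tau_rise) ** 2
           * np.tanh((params.twitch_duration - ts) / params.tau_decay) ** 2)
    out = np.where(inside, phi, 0.0)
    return out if out.ndim else float(out)


def active_stress_isometric(t, t_act, E, params: ActiveParams, scar_fraction=0.0):
    """Isometric active stress σ_a0 (kPa).

    σ_a0 = (1 − scar)·t_peak·max(0, 1 + β(λ − 1))·φ(t − t_act); always ≥ 0.
    Full scar produces no tension at any time.
    """
    E = np.asarray(E, dtype=float)
    lam = np.sqrt(1.0 + 2.0 * E)
    length_factor = np.maximum(0.0, 1.0 + params.beta * (lam - 1.0))
    out = ((1.0 - np.asarray(scar_fraction)) * params.t_peak_stress
           * length_factor * twitch(np.asarray(t) - np.asarray(t_act), params))
    return out if np.ndim(out) else float(out)


def passive_stress(E, params: PassiveParams, scar_fraction=0.0):
    """Passive fibre stress σ_p = k_eff·(exp(bE) − 1) (kPa); zero at E = 0."""
    E = np.asarray(E, dtype=float)
    if np.any(E <= -0.5):
        raise ValueError("Green strain must satisfy E > -0.5 (positive squared stretch)")
    out = params.k_eff(scar_fraction) * np.expm1(params.b * E)
    return out if out.ndim else float(out)


def passive_stress_derivative(E, params: PassiveParams, scar_fraction=0.0):
    E = np.asarray(E, dtype=float)
    out = params.k_eff(scar_fraction) * params.b * np.exp(params.b * E)
    return out if out.ndim else float(out)


def passive_energy(E, params: PassiveParams, scar_fraction=0.0):
    """Stored passive energy density U_p(E) (kPa ≡ mJ/mL), U_p(0) = 0.

    U_p = (k_eff/b)·(exp(bE) − 1) − k_eff·E, the potential of σ_p.
    """
    E = np.asarray(E, dtype=float)
    k_eff = params.k_eff(scar_fraction)
    out = (k_eff / params.b) * np.expm1(params.b * E) - k_eff * E
    return out if out.ndim else float(out)


def strain_rate_law(sigma_required, sigma_a0, sigma_p, params: ActiveParams):
    """Strain-rate closure Ė = (σ_req − σ_p − σ_a0)/(η + a_v·σ_a0)  (ms⁻¹).

    Inverts the carried-stress relation σ_req = σ_p + σ_a0 + (η + a_v σ_a0)·Ė:
    a linear force–velocity correction on the active stress plus a parallel
    viscosity.  A segment asked to carry less than its internal stress
    shortens (Ė < 0).
    """
    sigma_a0 = np.asarray(sigma_a0, dtype=float)
    denom = params.eta + params.a_v * sigma_a0
    if np.any(denom <= 0):
        raise ValueError("eta + a_v*sigma_a0 must be > 0")
    out = (np.asarray(sigma_required, dtype=float) - np.asarray(sigma_p) - sigma_a0) / denom
    return out if out.ndim else float(out)
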