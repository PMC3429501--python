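"""One-at-a-time sensitivity of the peak regional work rates.

Each continuous factor is perturbed by ±delta (default ±10%) around the
packaged defaults; binary factors toggle a switch (scar on/off).  For every
run the full pipeline is re-executed — patient generation, activation at
the baseline-calibrated conduction velocity, simulation — and the percent
change in the signed peak regional average work rate is reported for the
whole heart, LV free wall, RV and septum.

The factor list mirrors the model's personalised parameter surface; it is
the package's own reconstruction, not a published list.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .activation import ConductionParams
from .hemodynamics import ModelParams
from .pipeline import simulate_protocol
from .virtual_patient import PatientConfig, generate_patient
from .work_analysis import percent_change, regional_average, signed_peak, work_rate

__all__ = ["SensitivityResult", "oat_sensitivity", "DEFAULT_FACTORS",
           "SENSITIVITY_REGIONS"]

SENSITIVITY_REGIONS = ("whole_heart", "LV", "RV", "septum")


def _mp(setter):
    """Lift a ModelParams perturbation to the (config, params) pair."""
    return lambda cfg, mp, mult: (cfg, setter(mp, mult))


def _active(field):
    return _mp(lambda mp, m: mp.replace(
        active=mp.active.replace(**{field: getattr(mp.active, field) * m})))


def _passive(field):
    return _mp(lambda mp, m: mp.replace(
        passive=mp.passive.replace(**{field: getattr(mp.passive, field) * m})))


def _wk(which, field):
    def apply(mp, m):
        wk = getattr(mp, which)
        return mp.replace(**{which: wk.replace(**{field: getattr(wk, field) * m})})
    return _mp(apply)


#: factor name -> (kind, apply(config, params, multiplier) -> (config, params))
DEFAULT_FACTORS = {
    "t_peak_stress": ("continuous", _active("t_peak_stress")),
    "tau_rise": ("continuous", _active("tau_rise")),
    "tau_decay": ("continuous", _active("tau_decay")),
    "beta": ("continuous", _active("beta")),
    "a_v": ("continuous", _active("a_v")),
    "eta": ("continuous", _active("eta")),
    "passive_k": ("continuous", _passive("k")),
    "passive_b": ("continuous", _passive("b")),
    "scar_stiffness_multiplier": ("continuous", _passive("scar_stiffness_multiplier")),
    "scar_velocity_factor": ("continuous", _mp(lambda mp, m: mp.replace(
        conduction=ConductionParams(mp.conduction.velocity,
                                    min(1.0, mp.conduction.scar_velocity_factor * m))))),
    "conduction_velocity": ("continuous", _mp(lambda mp, m: mp.replace(
        conduction=ConductionParams(mp.conduction.velocity * m,
                                    mp.conduction.scar_velocity_factor)))),
    "r_c_systemic": ("continuous", _wk("wk_sys", "proximal_resistance")),
    "r_p_systemic": ("continuous", _wk("wk_sys", "peripheral_resistance")),
    "c_systemic": ("continuous", _wk("wk_sys", "compliance")),
    "lv_edv": ("continuous", lambda cfg, mp, m: (
        cfg.replace(lv_edv_ml=cfg.lv_edv_ml * m), mp)),
    "lv_wall_volume": ("continuous", lambda cfg, mp, m: (
        cfg.replace(lv_wall_volume_ml=cfg.lv_wall_volume_ml * m), mp)),
    "scar": ("binary", lambda cfg, mp, m: (
        cfg.replace(scar=replace(cfg.scar, fraction=0.0)), mp)),
}


@dataclass(frozen=True)
class SensitivityResult:
    factor: str
    direction: str            # minus10 | plus10 | binary
    percent_change_peak_work_rate: dict   # region -> %


def _peaks(config: PatientConfig, params: ModelParams, protocol: str,
           seed: int, dt: float, conduction) -> dict:
    patient = generate_patient(config, seed=seed)
    result = simulate_protocol(patient, protocol, params, dt=dt,
                               conduction=conduction)
    wt = work_rate(result.trace)
    return {region: signed_peak(regional_average(
        wt.w, region, patient, result.trace.segment_ids))
        for region in SENSITIVITY_REGIONS}, result.conduction


def oat_sensitivity(base_config: PatientConfig | None = None,
                    base_params: ModelParams | None = None,
                    factors=None, delta: float = 0.10,
                    protocol: str = "sinus", seed: int = 1,
                    dt: float = 1.0) -> list:
    """One-at-a-time ±delta perturbation of each factor.

    The baseline run is shared: its calibrated conduction velocity is reused
    for every perturbed run (perturbations hold everything else fixed), and
    results are fully deterministic given ``seed``.  Unknown factor names
    raise with the list of valid ones.  Run count:
    1 + 2·n_continuous + n_binary.
    """
    from .hemodynamics import default_model_params

    if not (0.0 <= delta < 1.0):
        raise ValueError("delta must be in [0, 1)")
    base_config = base_config or PatientConfig()
    base_params = base_params or default_model_params()
    if factors is None:
        factors = list(DEFAULT_FACTORS)
    unknown = [f for f in factors if f not in DEFAULT_FACTORS]
    if unknown:
        raise ValueError(f"unknown sensitivity factors {unknown}; valid factors: "
                         f"{sorted(DEFAULT_FACTORS)}")

    base_peaks, conduction = _peaks(base_config, base_params, protocol, seed,
                                    dt, conduction=None)
    # the baseline-calibrated velocity becomes part of the perturbed params
    base_params = base_params.replace(conduction=conduction)

    results = []
    for name in factors:
        kind, apply = DEFAULT_FACTORS[name]
        if kind == "binary":
            directions = (("binary", 1.0),)
        else:
            directions = (("minus10", 1.0 - delta), ("plus10", 1.0 + delta))
        for direction, mult in directions:
            cfg, mp = apply(base_config, base_params, mult)
            peaks, _ = _peaks(cfg, mp, protocol, seed, dt,
                              conduction=mp.conduction)
            changes = {region: percent_change(base_peaks[region], peaks[region])
                       for region in SENSITIVITY_REGIONS}
            results.append(SensitivityResult(
                factor=name, direction=direction,
                percent_change_peak_work_rate=changes))
    return results
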