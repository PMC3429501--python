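"""Readers, writers, run configuration and seed management.

All numeric fields round-trip losslessly at double precision: JSON numbers
are written with full repr precision and CSV files use '.' decimals, comma
separators and a header row.  One top-level seed is split hierarchically so
every stochastic stage (patient generation, measurement noise) is
reproducible from a single integer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd

from .activation import ActivationMap
from .constitutive import ActiveParams, PassiveParams
from .hemodynamics import (PHASE_NAMES, ModelParams, SimulationTrace,
                           WindkesselParams)
from .virtual_patient import PatientConfig, Segment, VirtualPatient
from .work_analysis import RegionalWorkSummary

__all__ = [
    "write_patient", "read_patient",
    "write_constitutive_params", "read_constitutive_params",
    "write_model_params", "read_model_params",
    "write_trace", "read_trace",
    "write_activation_map", "read_activation_map",
    "write_summary", "read_summary",
    "RunConfig", "split_seed",
]

log = logging.getLogger(__name__)

_PATIENT_KEYS = {"segments", "lv_edv_ml", "rv_edv_ml", "edp_lv_kpa",
                 "edp_rv_kpa", "sinus_rate_bpm", "paced_rate_bpm",
                 "av_delay_ms", "seed"}
_SEGMENT_KEYS = {"id", "wall", "region", "wall_volume_ml", "ref_area_cm2",
                 "thickness_cm", "scar_fraction", "centroid_cm"}
_CONSTITUTIVE_KEYS = ("t_peak_stress_kpa", "tau_rise_ms", "tau_decay_ms",
                      "twitch_duration_ms", "beta", "a_v_ms", "eta_kpa_ms",
                      "k_kpa", "b", "scar_stiffness_multiplier")


class ParseError(ValueError):
    """Raised on malformed artifact files."""


def _load_json(path) -> dict:
    with open(path) as fh:
        try:
            return json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: line {exc.lineno}, column {exc.colno}: "
                             f"{exc.msg}") from exc


# --------------------------------------------------------------------------
# patient

def write_patient(patient: VirtualPatient, path) -> None:
    doc = {
        "segments": [{
            "id": s.id, "wall": s.wall, "region": s.region,
            "wall_volume_ml": s.wall_volume, "ref_area_cm2": s.ref_midwall_area,
            "thickness_cm": s.thickness, "scar_fraction": s.scar_fraction,
            "centroid_cm": list(s.centroid),
        } for s in patient.segments],
        "lv_edv_ml": patient.lv_edv, "rv_edv_ml": patient.rv_edv,
        "edp_lv_kpa": patient.end_diastolic_pressure_lv,
        "edp_rv_kpa": patient.end_diastolic_pressure_rv,
        "sinus_rate_bpm": patient.sinus_rate, "paced_rate_bpm": patient.paced_rate,
        "av_delay_ms": patient.av_delay, "seed": patient.seed,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _layout_fields(doc_segments):
    """Reconstruct layout columns/levels from region membership and id order
    (the generator assigns ids level-by-level within each region)."""
    by_region = {}
    for seg in doc_segments:
        by_region.setdefault(seg["region"], []).append(seg["id"])
    from .virtual_patient import COLUMNS
    layout = {}
    for region, ids in by_region.items():
        ids = sorted(ids)
        for level, sid in enumerate(ids):
            if region == "LV_apex":
                layout[sid] = (COLUMNS[level % len(COLUMNS)], len(ids) - 1)
            elif region in ("septum", "RV"):
                layout[sid] = (region if region == "septum" else "RV", level)
            else:
                layout[sid] = (region, level)
    return layout


def read_patient(path, septum_cap_height_cm: float = 0.8,
                 qrs_duration_ms: float = 154.0) -> VirtualPatient:
    """Read a patient JSON.

    The reference-shell bookkeeping (junction radius, unloaded cap heights)
    is not part of the file schema; it is reconstructed from the stored
    segment areas given the unloaded septal cap height, which for files
    written by this package recovers the generator's values to round-off.
    """
    doc = _load_json(path)
    unknown = set(doc) - _PATIENT_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown patient keys {sorted(unknown)}")
    missing = _PATIENT_KEYS - set(doc)
    if missing:
        raise ParseError(f"{path}: missing patient keys {sorted(missing)}")
    layout = _layout_fields(doc["segments"])
    segments = []
    for sd in doc["segments"]:
        unknown = set(sd) - _SEGMENT_KEYS
        if unknown:
            raise ParseError(f"{path}: unknown segment keys {sorted(unknown)}")
        column, level = layout[sd["id"]]
        segments.append(Segment(
            id=int(sd["id"]), wall=sd["wall"], region=sd["region"],
            wall_volume=float(sd["wall_volume_ml"]),
            ref_midwall_area=float(sd["ref_area_cm2"]),
            thickness=float(sd["thickness_cm"]),
            scar_fraction=float(sd["scar_fraction"]),
            centroid=tuple(sd["centroid_cm"]), column=column, level=level))

    import math
    wall_area = {w: sum(s.ref_midwall_area for s in segments if s.wall == w)
                 for w in ("LV_free_wall", "septum", "RV_free_wall")}
    x_s = septum_cap_height_cm
    y = math.sqrt(wall_area["septum"] / math.pi - x_s * x_s)
    x_l = -math.sqrt(wall_area["LV_free_wall"] / math.pi - y * y)
    x_r = math.sqrt(wall_area["RV_free_wall"] / math.pi - y * y)

    return VirtualPatient(
        segments=tuple(segments),
        lv_edv=float(doc["lv_edv_ml"]), rv_edv=float(doc["rv_edv_ml"]),
        end_diastolic_pressure_lv=float(doc["edp_lv_kpa"]),
        end_diastolic_pressure_rv=float(doc["edp_rv_kpa"]),
        sinus_rate=float(doc["sinus_rate_bpm"]),
        paced_rate=float(doc["paced_rate_bpm"]),
        av_delay=float(doc["av_delay_ms"]), seed=int(doc["seed"]),
        junction_radius_cm=y, unloaded_cap_heights_cm=(x_l, x_s, x_r),
        qrs_duration_ms=qrs_duration_ms)


# --------------------------------------------------------------------------
# parameters

def write_constitutive_params(active: ActiveParams, passive: PassiveParams,
                              path) -> None:
    doc = {
        "t_peak_stress_kpa": active.t_peak_stress,
        "tau_rise_ms": active.tau_rise, "tau_decay_ms": active.tau_decay,
        "twitch_duration_ms": active.twitch_duration, "beta": active.beta,
        "a_v_ms": active.a_v, "eta_kpa_ms": active.eta,
        "k_kpa": passive.k, "b": passive.b,
        "scar_stiffness_multiplier": passive.scar_stiffness_multiplier,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_constitutive_params(path):
    doc = _load_json(path)
    unknown = set(doc) - set(_CONSTITUTIVE_KEYS)
    if unknown:
        raise ParseError(f"{path}: unknown parameter keys {sorted(unknown)}")
    active = ActiveParams(
        t_peak_stress=doc["t_peak_stress_kpa"], tau_rise=doc["tau_rise_ms"],
        tau_decay=doc["tau_decay_ms"], twitch_duration=doc["twitch_duration_ms"],
        beta=doc["beta"], a_v=doc["a_v_ms"], eta=doc["eta_kpa_ms"])
    passive = PassiveParams(k=doc["k_kpa"], b=doc["b"],
                            scar_stiffness_multiplier=doc["scar_stiffness_multiplier"])
    return active, passive


def write_model_params(params: ModelParams, path) -> None:
    doc = {
        "constitutive": {
            "t_peak_stress_kpa": params.active.t_peak_stress,
            "tau_rise_ms": params.active.tau_rise,
            "tau_decay_ms": params.active.tau_decay,
            "twitch_duration_ms": params.active.twitch_duration,
            "beta": params.active.beta, "a_v_ms": params.active.a_v,
            "eta_kpa_ms": params.active.eta, "k_kpa": params.passive.k,
            "b": params.passive.b,
            "scar_stiffness_multiplier": params.passive.scar_stiffness_multiplier,
        },
        "windkessel_systemic": asdict(params.wk_sys),
        "windkessel_pulmonary": asdict(params.wk_pul),
        "conduction": {"velocity_cm_per_ms": params.conduction.velocity,
                       "scar_velocity_factor": params.conduction.scar_velocity_factor},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_model_params(path) -> ModelParams:
    from .activation import ConductionParams
    doc = _load_json(path)
    c = doc["constitutive"]
    active = ActiveParams(
        t_peak_stress=c["t_peak_stress_kpa"], tau_rise=c["tau_rise_ms"],
        tau_decay=c["tau_decay_ms"], twitch_duration=c["twitch_duration_ms"],
        beta=c["beta"], a_v=c["a_v_ms"], eta=c["eta_kpa_ms"])
    passive = PassiveParams(k=c["k_kpa"], b=c["b"],
                            scar_stiffness_multiplier=c["scar_stiffness_multiplier"])
    return ModelParams(
        active=active, passive=passive,
        wk_sys=WindkesselParams(**doc["windkessel_systemic"]),
        wk_pul=WindkesselParams(**doc["windkessel_pulmonary"]),
        conduction=ConductionParams(doc["conduction"]["velocity_cm_per_ms"],
                                    doc["conduction"]["scar_velocity_factor"]))


# --------------------------------------------------------------------------
# traces and maps

def write_trace(trace: SimulationTrace, path) -> None:
    # %.17g round-trips IEEE doubles exactly
    trace.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trace(path) -> SimulationTrace:
    """Reconstruct a trace from its CSV.

    Flows are recovered from the volume differences; the cap-geometry
    diagnostic columns are object-level only and read back as zeros.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    name_to_code = {v: k for k, v in PHASE_NAMES.items()}
    seg_ids = np.array(sorted(
        int(c[2:]) for c in df.columns if c.startswith("E_")))
    n = len(df)

    def grid(prefix):
        return np.stack([df[f"{prefix}_{i}"].to_numpy() for i in seg_ids], axis=1)

    time = df["time_ms"].to_numpy(dtype=float)
    v_lv = df["v_lv_ml"].to_numpy(dtype=float)
    v_rv = df["v_rv_ml"].to_numpy(dtype=float)
    dt = time[1] - time[0] if n > 1 else 1.0
    q_sys = np.zeros(n)
    q_pul = np.zeros(n)
    q_sys[1:] = -np.diff(v_lv) / dt
    q_pul[1:] = -np.diff(v_rv) / dt
    return SimulationTrace(
        time=time, segment_ids=seg_ids,
        E=grid("E"), Edot=grid("Edot"), sigma_a=grid("sa"), sigma_p=grid("sp"),
        p_lv=df["p_lv_kpa"].to_numpy(dtype=float), v_lv=v_lv,
        phase_lv=np.array([name_to_code[s] for s in df["phase_lv"]], dtype=np.int8),
        p_rv=df["p_rv_kpa"].to_numpy(dtype=float), v_rv=v_rv,
        phase_rv=np.array([name_to_code[s] for s in df["phase_rv"]], dtype=np.int8),
        p_art_sys=df["p_art_sys_kpa"].to_numpy(dtype=float),
        p_art_pul=df["p_art_pul_kpa"].to_numpy(dtype=float),
        q_sys=q_sys, q_pul=q_pul, geometry=np.zeros((n, 4)))


def write_activation_map(amap: ActivationMap, path) -> None:
    pd.DataFrame({"segment_id": amap.segment_ids,
                  "t_act_ms": amap.t_act}).to_csv(path, index=False,
                                                  float_format="%.17g")


def read_activation_map(path) -> ActivationMap:
    df = pd.read_csv(path, float_precision="round_trip")
    return ActivationMap(segment_ids=df["segment_id"].to_numpy(dtype=int),
                         t_act=df["t_act_ms"].to_numpy(dtype=float))


def write_summary(summary: RegionalWorkSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.data, fh, indent=1)


def read_summary(path) -> RegionalWorkSummary:
    return RegionalWorkSummary(data=_load_json(path))


# --------------------------------------------------------------------------
# run configuration and seeds

_RUNCONFIG_FIELDS = None


@dataclass(frozen=True)
class RunConfig:
    """Schema-validated settings for a reproducible pipeline run."""
    seed: int = 1
    protocols: tuple = ("sinus", "crt")
    dt_ms: float = 1.0
    duration_ms: float = 400.0
    out_dir: str = "runs"
    log_level: str = "INFO"
    patient: dict = field(default_factory=dict)    # PatientConfig overrides

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(doc) - valid
        if unknown:
            raise ParseError(f"unknown run-config keys {sorted(unknown)}; "
                             f"valid keys: {sorted(valid)}")
        cfg = cls(**{k: (tuple(v) if k == "protocols" else v)
                     for k, v in doc.items()})
        patient_fields = {f.name for f in fields(PatientConfig)}
        unknown = set(cfg.patient) - patient_fields
        if unknown:
            raise ParseError(f"unknown patient keys {sorted(unknown)} "
                             f"under 'patient'")
        return cfg

    def patient_config(self) -> PatientConfig:
        return PatientConfig(**self.patient)


def split_seed(seed: int, n: int) -> list:
    """Derive ``n`` independent child seeds (< 2**31) from one top-level seed."""
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]
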