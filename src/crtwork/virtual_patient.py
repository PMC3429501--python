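"""Synthetic virtual-patient generator.

No clinical data ship with this package.  This module builds a segment-based
biventricular geometry plus emulated catheter-lab measurements with the
structure the downstream analysis assumes: a dilated LV (EF ≈ 25% once the
default simulation is run), sinus LBBB timing with a 154 ms QRS target, a
small apical septal subendocardial scar, and a 500 Hz LV pressure wire.

Geometry is deliberately idealised: three mechanical walls (LV free wall,
septum, RV free wall) modelled as spherical caps sharing a junction circle.
Each wall is divided into segments; segment centroids live on two nested
idealised shells and are used ONLY for inter-segment distances in the
activation stage.

Layout (n = segments per region, default 4): four circumferential columns
(anterior, lateral, posterior, septum) of n levels each from base to apex,
n apical-cap segments (region LV_apex, one attached to each column), and an
RV free-wall column of n levels facing the septum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .units import MMHG_PER_KPA

__all__ = [
    "Segment",
    "VirtualPatient",
    "MeasurementSet",
    "PatientConfig",
    "ScarDescriptor",
    "NoiseSettings",
    "generate_patient",
    "default_patient",
    "synthesize_measurements",
    "LV_COLUMNS",
    "COLUMNS",
    "REGIONS",
]

#: circumferential ring order (consecutive columns are neighbours, with wrap)
COLUMNS = ("LV_anterior", "LV_lateral", "LV_posterior", "septum")
LV_COLUMNS = ("LV_anterior", "LV_lateral", "LV_posterior")
REGIONS = ("LV_lateral", "LV_anterior", "LV_posterior", "LV_apex", "septum", "RV")

_COLUMN_ANGLE_DEG = {"LV_anterior": 90.0, "LV_lateral": 0.0,
                     "LV_posterior": 270.0, "septum": 180.0}


class ConfigurationError(ValueError):
    """Raised when generation settings are inconsistent; names the field."""


@dataclass(frozen=True)
class Segment:
    id: int
    wall: str                 # LV_free_wall | septum | RV_free_wall
    region: str               # one of REGIONS
    wall_volume: float        # mL (reference)
    ref_midwall_area: float   # cm² (reference, unloaded)
    thickness: float          # cm (reference)
    scar_fraction: float      # in [0, 1]
    centroid: tuple           # (x, y, z) cm — used only for distances
    column: str = ""          # layout column ("" for RV / apex bookkeeping)
    level: int = 0            # 0 = base … n-1 = most apical


@dataclass(frozen=True)
class ScarDescriptor:
    """Scar as a per-segment volume fraction, localised by (region, levels)."""
    region: str = "septum"
    levels: tuple = (-1,)     # -1 means the most apical level of the column
    fraction: float = 0.35


@dataclass(frozen=True)
class NoiseSettings:
    pressure_sd_mmhg: float = 1.0
    activation_jitter_ms: float = 2.0
    qrs_jitter_ms: float = 0.0
    pv_pressure_sd_kpa: float = 0.0

    def validate(self) -> None:
        for name in ("pressure_sd_mmhg", "activation_jitter_ms",
                     "qrs_jitter_ms", "pv_pressure_sd_kpa"):
            if getattr(self, name) < 0:
                raise ValueError(f"NoiseSettings.{name} must be >= 0")


@dataclass(frozen=True)
class PatientConfig:
    """Generation settings for the synthetic patient.

    Volumes reflect the dilated-cardiomyopathy phenotype (severe systolic
    dysfunction): LV EDV 280 mL, LV wall 170 mL, unloaded cavity 150 mL.
    These are package defaults chosen from the phenotype, not measurements
    of any patient.
    """

    n_per_region: int = 4
    lv_wall_volume_ml: float = 170.0
    septum_wall_fraction: float = 0.30
    rv_wall_volume_ml: float = 45.0
    lv_edv_ml: float = 280.0
    rv_edv_ml: float = 160.0
    lv_unloaded_volume_ml: float = 150.0
    rv_unloaded_volume_ml: float = 90.0
    junction_radius_cm: float = 3.6
    septum_cap_height_cm: float = 0.8
    edp_lv_kpa: float = 1.9
    edp_rv_kpa: float = 0.75
    sinus_rate_bpm: float = 69.0
    paced_rate_bpm: float = 100.0
    av_delay_ms: float = 100.0
    qrs_duration_ms: float = 154.0
    scar: ScarDescriptor = field(default_factory=ScarDescriptor)
    jitter: float = 0.05      # relative jitter on per-segment area/volume splits

    def validate(self) -> None:
        positive = ("n_per_region", "lv_wall_volume_ml", "rv_wall_volume_ml",
                    "lv_edv_ml", "rv_edv_ml", "lv_unloaded_volume_ml",
                    "rv_unloaded_volume_ml", "junction_radius_cm",
                    "sinus_rate_bpm", "paced_rate_bpm", "qrs_duration_ms")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"PatientConfig.{name} must be > 0")
        if not (0.0 < self.septum_wall_fraction < 1.0):
            raise ConfigurationError("PatientConfig.septum_wall_fraction must be in (0, 1)")
        if not (0.0 <= self.scar.fraction <= 1.0):
            raise ConfigurationError("PatientConfig.scar.fraction must be in [0, 1]")
        if self.scar.region not in REGIONS:
            raise ConfigurationError(f"PatientConfig.scar.region must be one of {REGIONS}")
        if self.jitter < 0 or self.jitter >= 0.5:
            raise ConfigurationError("PatientConfig.jitter must be in [0, 0.5)")

    def replace(self, **kw) -> "PatientConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class VirtualPatient:
    segments: tuple
    lv_edv: float
    rv_edv: float
    end_diastolic_pressure_lv: float
    end_diastolic_pressure_rv: float
    sinus_rate: float
    paced_rate: float
    av_delay: float
    seed: int
    # reference-shell bookkeeping consumed by the mechanics stage
    junction_radius_cm: float = 3.6
    unloaded_cap_heights_cm: tuple = (0.0, 0.0, 0.0)   # (x_LVFW, x_SEPT, x_RVFW)
    qrs_duration_ms: float = 154.0

    # -- convenience views -------------------------------------------------
    def segment_ids(self):
        return np.array([s.id for s in self.segments])

    def segments_in_region(self, region: str):
        segs = [s for s in self.segments if s.region == region]
        if not segs:
            raise ValueError(f"region {region!r} is empty")
        return segs

    def segments_in_wall(self, wall: str):
        return [s for s in self.segments if s.wall == wall]

    def wall_volumes(self):
        return np.array([s.wall_volume for s in self.segments])

    def scar_fractions(self):
        return np.array([s.scar_fraction for s in self.segments])


@dataclass(frozen=True)
class MeasurementSet:
    """Emulated catheter-lab measurements."""
    lv_pressure_time_ms: np.ndarray     # 500 Hz grid
    lv_pressure_mmhg: np.ndarray
    atrial_filling_pv: tuple            # ((P kPa, V mL), ...) monotone in V
    endocardial_activation_samples: tuple   # ((segment id, t ms), ...)
    qrs_duration: float                 # ms
    ejection_pv: tuple                  # ((P kPa, V mL), ...) during LV ejection


# --------------------------------------------------------------------------
# geometry helpers

def _cap_volume(x: float, y: float) -> float:
    """Signed spherical-cap volume (mL) for cap height x over a circle of radius y."""
    return (math.pi / 6.0) * x * (x * x + 3.0 * y * y)


def _solve_cap_height(target_volume: float, y: float, lo: float, hi: float) -> float:
    f = lambda x: _cap_volume(x, y) - target_volume
    return brentq(f, lo, hi, xtol=1e-12)


def _reference_shell(config: PatientConfig):
    """Unloaded cap heights (x_L < 0, x_S, x_R) and wall areas from the config."""
    y = config.junction_radius_cm
    x_s = config.septum_cap_height_cm
    v_s = _cap_volume(x_s, y)
    # V_LV = Vm(x_S) − Vm(x_L);  V_RV = Vm(x_R) − Vm(x_S)
    x_l = _solve_cap_height(v_s - config.lv_unloaded_volume_ml, y, -40.0, -1e-6)
    x_r = _solve_cap_height(config.rv_unloaded_volume_ml + v_s, y, 1e-6, 40.0)
    areas = {w: math.pi * (x * x + y * y)
             for w, x in (("LV_free_wall", x_l), ("septum", x_s), ("RV_free_wall", x_r))}
    return (x_l, x_s, x_r), areas


def _centroid(column: str, level: int, n_levels: int, apex: bool = False,
              rv: bool = False) -> tuple:
    """Centroid on nested idealised shells; only relative distances matter."""
    long_axis = 9.0
    r0 = 3.8
    if apex:
        z = long_axis * 0.95
        r = 0.8
    else:
        z = long_axis * (0.5 + level) / (n_levels + 1.0)
        r = r0 * math.sqrt(max(0.05, 1.0 - (z / long_axis) ** 2))
    ang = math.radians(_COLUMN_ANGLE_DEG["septum" if rv else column])
    if rv:
        r = r + 2.5
    return (r * math.cos(ang), r * math.sin(ang), z)


def _split(total: float, n: int, rng: np.random.Generator, jitter: float) -> np.ndarray:
    w = 1.0 + jitter * rng.uniform(-1.0, 1.0, size=n)
    return total * w / w.sum()


# --------------------------------------------------------------------------
# public operations

def generate_patient(config: PatientConfig | None = None, seed: int = 1) -> VirtualPatient:
    """Generate a virtual patient; deterministic given (config, seed)."""
    config = config or PatientConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_per_region

    (x_l, x_s, x_r), wall_areas = _reference_shell(config)

    sept_wall = config.lv_wall_volume_ml * config.septum_wall_fraction
    lvfw_wall = config.lv_wall_volume_ml - sept_wall

    segments = []
    next_id = 0

    def add(wall, region, column, level, area, volume, centroid):
        nonlocal next_id
        segments.append(Segment(
            id=next_id, wall=wall, region=region, wall_volume=volume,
            ref_midwall_area=area, thickness=volume / area,
            scar_fraction=0.0, centroid=centroid, column=column, level=level))
        next_id += 1

    # LV free wall: three columns of n levels + n apical segments, all one
    # mechanical wall sharing the LVFW cap area.
    n_lvfw = 3 * n + n
    lvfw_areas = _split(wall_areas["LV_free_wall"], n_lvfw, rng, config.jitter)
    lvfw_vols = _split(lvfw_wall, n_lvfw, rng, config.jitter)
    k = 0
    for column in LV_COLUMNS:
        for level in range(n):
            add("LV_free_wall", column, column, level, lvfw_areas[k],
                lvfw_vols[k], _centroid(column, level, n))
            k += 1
    for j in range(n):
        col = COLUMNS[j % len(COLUMNS)]
        add("LV_free_wall", "LV_apex", col, n - 1, lvfw_areas[k],
            lvfw_vols[k], _centroid(col, n - 1, n, apex=True))
        k += 1

    sept_areas = _split(wall_areas["septum"], n, rng, config.jitter)
    sept_vols = _split(sept_wall, n, rng, config.jitter)
    for level in range(n):
        add("septum", "septum", "septum", level, sept_areas[level],
            sept_vols[level], _centroid("septum", level, n))

    rv_areas = _split(wall_areas["RV_free_wall"], n, rng, config.jitter)
    rv_vols = _split(config.rv_wall_volume_ml, n, rng, config.jitter)
    for level in range(n):
        add("RV_free_wall", "RV", "RV", level, rv_areas[level],
            rv_vols[level], _centroid("septum", level, n, rv=True))

    # scar: localised to the named region/levels, zero elsewhere
    scar_levels = {lv if lv >= 0 else n - 1 for lv in config.scar.levels}
    segments = [
        replace(s, scar_fraction=config.scar.fraction)
        if (s.region == config.scar.region and s.level in scar_levels
            and s.column == ("septum" if config.scar.region == "septum" else s.column))
        else s
        for s in segments
    ]

    patient = VirtualPatient(
        segments=tuple(segments),
        lv_edv=config.lv_edv_ml, rv_edv=config.rv_edv_ml,
        end_diastolic_pressure_lv=config.edp_lv_kpa,
        end_diastolic_pressure_rv=config.edp_rv_kpa,
        sinus_rate=config.sinus_rate_bpm, paced_rate=config.paced_rate_bpm,
        av_delay=config.av_delay_ms, seed=seed,
        junction_radius_cm=config.junction_radius_cm,
        unloaded_cap_heights_cm=(x_l, x_s, x_r),
        qrs_duration_ms=config.qrs_duration_ms,
    )
    _check_invariants(patient)
    return patient


def default_patient() -> VirtualPatient:
    """The packaged reference patient (sinus 69 bpm, paced 100 bpm, AV 100 ms).

    Geometry and the default constitutive parameters in :mod:`crtwork.constitutive`
    / :mod:`crtwork.hemodynamics` were tuned together (see docs/methods.md) so
    that the calibrated baseline simulation ejects with EF ≈ 25%.
    """
    return generate_patient(PatientConfig(), seed=1)


def _check_invariants(patient: VirtualPatient) -> None:
    ids = [s.id for s in patient.segments]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("segment ids must be unique")
    for region in REGIONS:
        if not any(s.region == region for s in patient.segments):
            raise ConfigurationError(f"region {region} is empty")
    for s in patient.segments:
        if s.wall_volume <= 0:
            raise ConfigurationError(f"segment {s.id}: wall_volume must be > 0")
        if s.thickness <= 0:
            raise ConfigurationError(f"segment {s.id}: thickness must be > 0")
        if not (0.0 <= s.scar_fraction <= 1.0):
            raise ConfigurationError(f"segment {s.id}: scar_fraction outside [0, 1]")
        if (s.region == "septum") != (s.wall == "septum"):
            raise ConfigurationError(f"segment {s.id}: septum region/wall mismatch")
        if (s.region == "RV") != (s.wall == "RV_free_wall"):
            raise ConfigurationError(f"segment {s.id}: RV region/wall mismatch")


def synthesize_measurements(patient: VirtualPatient, true_params, noise: NoiseSettings,
                            seed: int = 1, base_trace=None, activation_map=None
                            ) -> MeasurementSet:
    """Forward-simulate the patient at ``true_params`` and corrupt the outputs.

    ``base_trace``/``activation_map`` may be passed to reuse an existing
    baseline simulation (e.g. when drawing many noise realisations); they must
    have been produced from the same patient and parameters.
    """
    noise.validate()
    rng = np.random.default_rng(seed)

    from .pipeline import simulate_protocol  # lazy: avoids an import cycle

    if base_trace is None or activation_map is None:
        result = simulate_protocol(patient, "sinus", true_params)
        base_trace = result.trace
        activation_map = result.activation

    # 500 Hz pressure wire (2 ms sampling), mmHg, Gaussian noise
    t500 = np.arange(0.0, base_trace.time[-1] + 1e-9, 2.0)
    p_kpa = np.interp(t500, base_trace.time, base_trace.p_lv)
    p_mmhg = p_kpa * MMHG_PER_KPA + rng.normal(0.0, noise.pressure_sd_mmhg, t500.shape) \
        if noise.pressure_sd_mmhg > 0 else p_kpa * MMHG_PER_KPA

    # endocardial activation-time samples
    ids = activation_map.segment_ids
    t_act = activation_map.t_act
    jit = rng.normal(0.0, noise.activation_jitter_ms, t_act.shape) \
        if noise.activation_jitter_ms > 0 else np.zeros_like(t_act)
    samples = tuple((int(i), float(t + j)) for i, t, j in zip(ids, t_act, jit))

    span = float(t_act.max() - t_act.min())
    qrs = span + (float(rng.normal(0.0, noise.qrs_jitter_ms)) if noise.qrs_jitter_ms > 0 else 0.0)

    # atrial-filling PV points from quasi-static passive inflation
    from .calibration import passive_inflation_curve
    volumes = np.linspace(patient.lv_edv - 40.0, patient.lv_edv, 6)
    pressures = passive_inflation_curve(patient, true_params, volumes)
    if noise.pv_pressure_sd_kpa > 0:
        pressures = pressures + rng.normal(0.0, noise.pv_pressure_sd_kpa, pressures.shape)
    pv = tuple((float(p), float(v)) for p, v in zip(pressures, volumes))

    # ejection-phase PV samples from the simulated trace
    in_ej = base_trace.phase_lv == 1
    ej = tuple((float(p), float(v)) for p, v in
               zip(base_trace.p_lv[in_ej], base_trace.v_lv[in_ej]))

    return MeasurementSet(
        lv_pressure_time_ms=t500, lv_pressure_mmhg=np.asarray(p_mmhg),
        atrial_filling_pv=pv, endocardial_activation_samples=samples,
        qrs_duration=qrs, ejection_pv=ej)
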