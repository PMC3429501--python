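"""Regional myocardial work analysis.

The central quantity is the work rate per unit (reference) volume,

    w = σ_a · Ė   (kPa·ms⁻¹ ≡ kJ·m⁻³·ms⁻¹),

the product of the fibre active tension (second Piola–Kirchhoff, kPa) and
the Green strain rate (ms⁻¹).  Shortening under tension gives NEGATIVE w in
this convention — the summary table's work values are negative for a
working heart — while the three work MODES are the semantic surface:
non-working (no active tension: scar or not-yet-activated tissue),
positive work (tension + shortening, w < 0) and negative work (tension +
being stretched, w > 0).

Regions: ``LV`` is the whole LV free wall (lateral, anterior, posterior,
apex), ``septum`` and ``RV`` are their own walls, ``whole_heart`` is
everything; the four LV free-wall subregions are available by name.
Regional averages are wall-volume-weighted; the stored per-segment active
stress already averages scar and viable sub-volumes (scar contributes
zero), so plain volume weighting is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import passive_energy
from .hemodynamics import PHASE_IVC, ModelParams, SimulationTrace
from .units import J_PER_KPA_ML
from .virtual_patient import VirtualPatient

__all__ = [
    "MODE_NON_WORKING", "MODE_POSITIVE", "MODE_NEGATIVE",
    "TABLE_REGIONS", "LV_SUBREGIONS",
    "WorkTrace", "ModeFractionTrace", "RegionalWorkSummary", "EnergyBalance",
    "work_rate", "classify_modes", "regional_average", "mode_fractions",
    "total_work", "ejection_work", "energy_balance", "swap_work",
    "summary_table", "percent_change", "signed_peak", "region_member_ids",
]

MODE_NON_WORKING, MODE_POSITIVE, MODE_NEGATIVE = 0, 1, 2

TABLE_REGIONS = ("LV", "RV", "septum")
LV_SUBREGIONS = ("LV_posterior", "LV_apex", "LV_lateral", "LV_anterior")
_GROUPS = {
    "LV": ("LV_lateral", "LV_anterior", "LV_posterior", "LV_apex"),
    "septum": ("septum",),
    "RV": ("RV",),
    "whole_heart": ("LV_lateral", "LV_anterior", "LV_posterior", "LV_apex",
                    "septum", "RV"),
}
DEFAULT_EPS_TENSION = 0.1       # kPa, non-working threshold on active tension
DEFAULT_EPS_STRAIN_RATE = 2e-5  # ms⁻¹, stretch deadband for negative work
# (≈ 2% of the characteristic peak |Ė| of 1e-3 ms⁻¹; solver-level stretch
# jitter sits an order of magnitude below, sustained stretching well above)


@dataclass
class WorkTrace:
    time: np.ndarray
    segment_ids: np.ndarray
    w: np.ndarray          # (nt, nseg) kPa/ms
    mode: np.ndarray       # (nt, nseg) int8


@dataclass
class ModeFractionTrace:
    time: np.ndarray
    regions: tuple
    f_zero: np.ndarray     # (nt, nregions)
    f_pos: np.ndarray
    f_neg: np.ndarray

    def for_region(self, region: str):
        j = self.regions.index(region)
        return self.f_zero[:, j], self.f_pos[:, j], self.f_neg[:, j]


@dataclass
class RegionalWorkSummary:
    """Per-region systolic metrics for a sinus/paced pair of runs.

    ``data[region][metric] = {"sinus": v, "paced": v, "percent_change": v}``
    with metrics total_work (kJ·m⁻³), peak_avg_work_rate (kJ·m⁻³·ms⁻¹),
    peak_avg_strain_rate (ms⁻¹), peak_avg_active_tension (kPa) and
    peak_neg_fraction_ivc (dimensionless).
    """
    data: dict

    def metric(self, region: str, metric: str) -> dict:
        return self.data[region][metric]


@dataclass
class EnergyBalance:
    boundary_work: float       # ∫(P_LV dV_LV + P_RV dV_RV), mJ
    active_work: float         # Σ_i V_i ∫ σ_a Ė dt, mJ
    passive_stored: float      # Σ_i V_i ΔU_p, mJ
    viscous_dissipated: float  # Σ_i V_i ∫ (η + a_v σ_a) Ė² dt, mJ
    residual_fraction: float
    absolute_residual: bool = False   # True when boundary work was ~0


def region_member_ids(patient: VirtualPatient, region: str) -> np.ndarray:
    """Segment ids belonging to a named region or region group."""
    names = _GROUPS.get(region, (region,))
    ids = [s.id for s in patient.segments if s.region in names]
    if not ids:
        raise ValueError(f"region {region!r} is empty or unknown")
    return np.array(sorted(ids))


def _member_mask(patient: VirtualPatient, segment_ids: np.ndarray, region: str):
    members = set(region_member_ids(patient, region).tolist())
    return np.array([int(i) in members for i in segment_ids])


def work_rate(trace: SimulationTrace,
              eps_tension: float = DEFAULT_EPS_TENSION,
              eps_strain_rate: float = DEFAULT_EPS_STRAIN_RATE) -> WorkTrace:
    """Per-segment work-rate field w = σ_a·Ė with its mode classification.

    Only the ACTIVE stress enters (the passive contribution is stored
    elastically and recovered, so systolic work is reported "by active
    tension")."""
    w = trace.sigma_a * trace.Edot
    mode = classify_modes(trace, eps_tension, eps_strain_rate)
    return WorkTrace(time=trace.time, segment_ids=trace.segment_ids, w=w, mode=mode)


def classify_modes(trace: SimulationTrace,
                   eps_tension: float = DEFAULT_EPS_TENSION,
                   eps_strain_rate: float = DEFAULT_EPS_STRAIN_RATE) -> np.ndarray:
    """Work modes: σ_a < ε → non-working; else shortening (Ė ≤ 0) → positive
    work; being stretched (Ė > 0) → negative work.

    Ė = 0 ties are positive work by convention, and stretch rates below the
    ``eps_strain_rate`` deadband count as ties (pass 0 for the strict
    sign rule)."""
    if eps_tension <= 0:
        raise ValueError("eps_tension must be > 0")
    if eps_strain_rate < 0:
        raise ValueError("eps_strain_rate must be >= 0")
    mode = np.full(trace.sigma_a.shape, MODE_NON_WORKING, dtype=np.int8)
    active = trace.sigma_a >= eps_tension
    mode[active & (trace.Edot <= eps_strain_rate)] = MODE_POSITIVE
    mode[active & (trace.Edot > eps_strain_rate)] = MODE_NEGATIVE
    return mode


def regional_average(field: np.ndarray, region: str, patient: VirtualPatient,
                     segment_ids: np.ndarray | None = None) -> np.ndarray:
    """Wall-volume-weighted average of a per-segment field over a region.

    ``field`` has segments on its last axis, ordered by ``segment_ids``
    (defaults to ascending segment id)."""
    field = np.asarray(field)
    if segment_ids is None:
        segment_ids = np.array(sorted(s.id for s in patient.segments))
    mask = _member_mask(patient, segment_ids, region)
    vols = {s.id: s.wall_volume for s in patient.segments}
    v = np.array([vols[int(i)] for i in segment_ids])[mask]
    return field[..., mask] @ v / v.sum()


def mode_fractions(mode: np.ndarray, patient: VirtualPatient,
                   regions: tuple = ("LV", "RV", "septum"),
                   time: np.ndarray | None = None,
                   segment_ids: np.ndarray | None = None) -> ModeFractionTrace:
    """Volume fraction of each region in each work mode over time.

    The scar sub-volume of a segment (fraction f of its wall volume) is
    always non-working; the viable sub-volume (1 − f) follows the segment's
    classified mode.  The partition is exact: f_zero is computed as
    1 − f_pos − f_neg."""
    if segment_ids is None:
        segment_ids = np.array(sorted(s.id for s in patient.segments))
    by_id = {s.id: s for s in patient.segments}
    v = np.array([by_id[int(i)].wall_volume for i in segment_ids])
    f = np.array([by_id[int(i)].scar_fraction for i in segment_ids])
    nt = mode.shape[0]
    out = {m: np.zeros((nt, len(regions))) for m in (0, 1, 2)}
    for j, region in enumerate(regions):
        mask = _member_mask(patient, segment_ids, region)
        vv, ff, mm = v[mask], f[mask], mode[:, mask]
        vtot = vv.sum()
        viable = vv * (1.0 - ff)
        out[MODE_POSITIVE][:, j] = (mm == MODE_POSITIVE) @ viable / vtot
        out[MODE_NEGATIVE][:, j] = (mm == MODE_NEGATIVE) @ viable / vtot
        out[MODE_NON_WORKING][:, j] = (1.0 - out[MODE_POSITIVE][:, j]
                                       - out[MODE_NEGATIVE][:, j])
    return ModeFractionTrace(
        time=time if time is not None else np.arange(nt, dtype=float),
        regions=tuple(regions),
        f_zero=out[MODE_NON_WORKING], f_pos=out[MODE_POSITIVE],
        f_neg=out[MODE_NEGATIVE])


def total_work(avg_work_rate: np.ndarray, time: np.ndarray,
               window: tuple = (0.0, 400.0)) -> float:
    """Trapezoidal time integral of an average work-rate series (kJ·m⁻³)."""
    sel = (time >= window[0]) & (time <= window[1])
    return float(np.trapezoid(avg_work_rate[sel], time[sel]))


def ejection_work(pressure: np.ndarray, volume: np.ndarray) -> float:
    """Area of the closed PV loop (shoelace), in J.

    kPa·mL = mJ; positive for loops traversed counter-clockwise in the
    (V, P) plane (an ejecting ventricle)."""
    p = np.asarray(pressure, dtype=float)
    v = np.asarray(volume, dtype=float)
    area_kpa_ml = 0.5 * float(np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p))
    return area_kpa_ml * J_PER_KPA_ML


def energy_balance(trace: SimulationTrace, patient: VirtualPatient,
                   params: ModelParams) -> EnergyBalance:
    """Work-conservation check of a run: boundary (PV) work must equal the
    sum of active myocardial work, the change in stored passive energy and
    viscous dissipation.

    Returns the relative residual |active + ΔU_p + viscous − boundary| /
    |boundary|; all terms in mJ (kPa·mL).  With no boundary work the
    absolute residual is returned and flagged."""
    segs = sorted(patient.segments, key=lambda s: s.id)
    vols = np.array([s.wall_volume for s in segs])
    scar = np.array([s.scar_fraction for s in segs])
    dt = trace.dt

    dE = np.diff(trace.E, axis=0)
    sa = trace.sigma_a[1:]
    active = float(np.sum(vols * np.sum(sa * dE, axis=0)))
    visc_coeff = params.active.eta + params.active.a_v * sa
    viscous = float(np.sum(vols * np.sum(visc_coeff * (dE / dt) ** 2, axis=0)) * dt)
    u0 = passive_energy(trace.E[0], params.passive, scar)
    u1 = passive_energy(trace.E[-1], params.passive, scar)
    stored = float(np.sum(vols * (u1 - u0)))
    boundary = float(np.sum(trace.p_lv[1:] * np.diff(trace.v_lv))
                     + np.sum(trace.p_rv[1:] * np.diff(trace.v_rv)))

    mismatch = active + stored + viscous - boundary
    if abs(boundary) < 1e-9:
        return EnergyBalance(boundary, active, stored, viscous,
                             abs(mismatch), absolute_residual=True)
    return EnergyBalance(boundary, active, stored, viscous,
                         abs(mismatch) / abs(boundary))


def _common_grid(a: SimulationTrace, b: SimulationTrace):
    """Resample both traces' fields to the coarser of the two time grids."""
    coarse = a if a.dt >= b.dt else b
    t = coarse.time[coarse.time <= min(a.time[-1], b.time[-1])]

    def resample(tr, field):
        return np.stack([np.interp(t, tr.time, field[:, k])
                         for k in range(field.shape[1])], axis=1)
    return t, resample


def swap_work(tension_source: SimulationTrace, sr_source: SimulationTrace,
              patient: VirtualPatient,
              regions: tuple = ("LV", "RV", "septum", "whole_heart")) -> dict:
    """Cross-evaluated regional work rates: active tension from one run,
    strain rate from another.

    w_i(t) = σ_a,i^{tension}(t) · Ė_i^{SR}(t), regionally averaged.  The
    four (sinus/paced) × (sinus/paced) combinations reproduce the 2×2 swap
    layout; swap(A, A) is identical to the regional work rate of A.
    Returns {"time": t, region: series, ...}."""
    if not np.array_equal(tension_source.segment_ids, sr_source.segment_ids):
        raise ValueError("traces cover different segment sets")
    t, resample = _common_grid(tension_source, sr_source)
    sa = resample(tension_source, tension_source.sigma_a)
    edot = resample(sr_source, sr_source.Edot)
    w = sa * edot
    out = {"time": t}
    for region in regions:
        out[region] = regional_average(w, region, patient,
                                       tension_source.segment_ids)
    return out


def percent_change(sinus: float, paced: float) -> float:
    """Signed percentage change 100·(paced − sinus)/sinus.

    Signed division keeps an increase in work MAGNITUDE positive when both
    values are negative (e.g. −3.42 → −4.87 gives +42.4%).  A change from 0
    to 0 is 0; any other change from 0 is undefined (NaN)."""
    if sinus == 0:
        return 0.0 if paced == 0 else float("nan")
    return 100.0 * (paced - sinus) / sinus


def signed_peak(series: np.ndarray) -> float:
    """Extremum of largest absolute value, keeping its sign."""
    series = np.asarray(series)
    return float(series[np.argmax(np.abs(series))])


def _ivc_window(trace: SimulationTrace, region: str) -> np.ndarray:
    """IVC sample mask for a region: the window of the adjacent cavity (the
    septum uses the LV window)."""
    phase = trace.phase_rv if region == "RV" else trace.phase_lv
    return phase == PHASE_IVC


def summary_table(sinus: SimulationTrace, paced: SimulationTrace,
                  patient: VirtualPatient,
                  regions: tuple = TABLE_REGIONS,
                  eps_tension: float = DEFAULT_EPS_TENSION,
                  window: tuple = (0.0, 400.0)) -> RegionalWorkSummary:
    """Per-region systolic summary of a sinus/paced pair with signed
    percent changes, mirroring the five metric groups of the work table."""
    data = {}
    wt = {"sinus": work_rate(sinus, eps_tension), "paced": work_rate(paced, eps_tension)}
    traces = {"sinus": sinus, "paced": paced}
    mf = {k: mode_fractions(wt[k].mode, patient, regions, traces[k].time,
                            traces[k].segment_ids)
          for k in traces}
    for region in regions:
        metrics = {}
        vals = {}
        for k, tr in traces.items():
            avg_w = regional_average(wt[k].w, region, patient, tr.segment_ids)
            avg_sr = regional_average(tr.Edot, region, patient, tr.segment_ids)
            avg_sa = regional_average(tr.sigma_a, region, patient, tr.segment_ids)
            ivc = _ivc_window(tr, region)
            f_neg = mf[k].for_region(region)[2]
            vals[k] = {
                "total_work": total_work(avg_w, tr.time, window),
                "peak_avg_work_rate": signed_peak(avg_w),
                "peak_avg_strain_rate": signed_peak(avg_sr),
                "peak_avg_active_tension": signed_peak(avg_sa),
                "peak_neg_fraction_ivc": float(f_neg[ivc].max()) if ivc.any() else 0.0,
            }
        for name in vals["sinus"]:
            metrics[name] = {
                "sinus": vals["sinus"][name],
                "paced": vals["paced"][name],
                "percent_change": percent_change(vals["sinus"][name],
                                                 vals["paced"][name]),
            }
        data[region] = metrics
    return RegionalWorkSummary(data=data)
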