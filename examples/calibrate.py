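"""Personalise the model to (synthetic) catheter-lab measurements.

Synthesizes a noise-free measurement set from the packaged patient at known
parameters, then runs the three calibration stages in clinical order —
passive law from atrial-filling PV points, Windkessel from the ejection PV
relation, active twitch from the 500 Hz pressure transient — and reports
how well the known parameters are recovered.  (The active fit re-simulates
at every objective evaluation; expect ~a minute.)
"""

import numpy as np

from crtwork import (default_model_params, default_patient, simulate_protocol,
                     synthesize_measurements)
from crtwork.calibration import fit_active, fit_passive, fit_windkessel
from crtwork.units import KPA_PER_MMHG
from crtwork.virtual_patient import NoiseSettings

patient = default_patient()
truth = default_model_params()
base = simulate_protocol(patient, "sinus", truth)
ms = synthesize_measurements(patient, truth, NoiseSettings(0.0, 0.0, 0.0, 0.0),
                             seed=1, base_trace=base.trace,
                             activation_map=base.activation)

fp = fit_passive(ms.atrial_filling_pv, patient, truth)
print(f"passive:    k {fp.parameters.k:.3f} kPa (true {truth.passive.k}), "
      f"b {fp.parameters.b:.3f} (true {truth.passive.b})")

ej = base.trace.phase_lv == 1
fw = fit_windkessel(base.trace.time[ej], base.trace.p_lv[ej],
                    base.trace.v_lv[ej],
                    venous_pressure=truth.wk_sys.venous_pressure)
print(f"windkessel: Rc {fw.parameters.proximal_resistance:.2f} "
      f"(true {truth.wk_sys.proximal_resistance}), "
      f"Rp {fw.parameters.peripheral_resistance:.1f} "
      f"(true {truth.wk_sys.peripheral_resistance}), "
      f"C {fw.parameters.compliance:.2f} (true {truth.wk_sys.compliance})")

conditioned = truth.replace(
    passive=fp.parameters,
    wk_sys=truth.wk_sys.replace(
        proximal_resistance=fw.parameters.proximal_resistance,
        peripheral_resistance=fw.parameters.peripheral_resistance,
        compliance=fw.parameters.compliance))
fa = fit_active(ms.lv_pressure_time_ms, ms.lv_pressure_mmhg * KPA_PER_MMHG,
                patient, conditioned, base.activation)
print(f"active:     T_peak {fa.parameters.t_peak_stress:.1f} kPa "
      f"(true {truth.active.t_peak_stress}), "
      f"tau_rise {fa.parameters.tau_rise:.1f} ms (true {truth.active.tau_rise}), "
      f"tau_decay {fa.parameters.tau_decay:.1f} ms (true {truth.active.tau_decay})")

from crtwork.hemodynamics import run_simulation
calibrated = conditioned.replace(active=fa.parameters)
tr = run_simulation(patient, base.activation, calibrated)
p_meas = ms.lv_pressure_mmhg * KPA_PER_MMHG
rmse = np.sqrt(np.mean((np.interp(ms.lv_pressure_time_ms, tr.time, tr.p_lv)
                        - p_meas) ** 2))
print(f"calibrated pressure RMSE: {rmse:.3f} kPa "
      f"({100 * rmse / p_meas.max():.2f}% of peak)")
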