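"""Simulate one systole (end diastole → 400 ms) of the baseline patient.

Prints the phase timeline, pressures and the ejection fraction; writes the
full per-segment trace as CSV.
"""

import numpy as np

from crtwork import default_model_params, default_patient, simulate_protocol
from crtwork.hemodynamics import PHASE_EJECTION, PHASE_IVC
from crtwork.io import write_trace
from crtwork.units import MMHG_PER_KPA

patient = default_patient()
result = simulate_protocol(patient, "sinus", default_model_params())
tr = result.trace

ivc_end = int(np.argmax(tr.phase_lv == PHASE_EJECTION))
ej_end = int(np.argmax(tr.phase_lv == 2))
print(f"LV: IVC 0-{ivc_end} ms, ejection to {ej_end} ms, then isovolumetric")
print(f"peak LV pressure {tr.p_lv.max():.1f} kPa "
      f"({tr.p_lv.max() * MMHG_PER_KPA:.0f} mmHg), "
      f"EDP {tr.p_lv[0]:.2f} kPa")
print(f"LV volume {tr.v_lv[0]:.0f} -> {tr.v_lv.min():.0f} mL  "
      f"=> EF {tr.ejection_fraction_lv():.1f}%")
print(f"max dP/dt {np.diff(tr.p_lv).max() / tr.dt:.3f} kPa/ms")

write_trace(tr, "trace_sinus.csv")
print("wrote trace_sinus.csv (time, pressures, volumes, phases, per-segment "
      "strain/strain-rate/stresses)")
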