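"""Activation maps for sinus LBBB and CRT pacing.

Conduction velocity is calibrated by bisection so the sinus-LBBB map spans
the 154 ms QRS; CRT fuses a coronary-sinus LV-lateral paced wavefront with
the intrinsic one and should narrow the span markedly.
"""

from crtwork import default_patient
from crtwork.pipeline import activation_for_protocol

patient = default_patient()

sinus, _, conduction, graph = activation_for_protocol(patient, "sinus")
crt, _, _, _ = activation_for_protocol(patient, "crt", conduction=conduction,
                                       graph=graph)

print(f"calibrated conduction velocity: {conduction.velocity * 10:.2f} mm/ms")
print(f"sinus-LBBB span {sinus.span():.1f} ms | CRT span {crt.span():.1f} ms")
print("\nsegment  region        sinus t_act  crt t_act")
by_id = {s.id: s for s in patient.segments}
for sid, t_sin in sorted(sinus.as_dict().items()):
    seg = by_id[sid]
    print(f"{sid:7d}  {seg.region:12s} {t_sin:10.1f}  {crt.as_dict()[sid]:9.1f}")
print("\nLate lateral activation in sinus (LBBB pattern) is pulled forward "
      "by the LV pacing seed under CRT.")
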