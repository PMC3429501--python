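"""Unit conventions.

Internal units everywhere: kPa, mL, ms, cm.  With these, the work-rate unit
kPa·ms⁻¹ is identical to kJ·m⁻³·ms⁻¹ and kPa·mL is exactly 1 mJ, so energy
bookkeeping needs no conversion factors.  mmHg appears only in the emulated
500 Hz pressure-wire output.
"""

MMHG_PER_KPA = 7.50062
KPA_PER_MMHG = 1.0 / MMHG_PER_KPA

#: kPa·mL expressed in joule
J_PER_KPA_ML = 1.0e-3
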