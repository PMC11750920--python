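"""Export the RC network as a SPICE-dialect netlist.

Every airway unit maps to a capacitor (volume), every link to a resistor
(diffusional resistance) and four switched current sources (upwind
convection); the inlet sits behind a 1e100 s/cm3 blocking resistor.
"""

import mbwsim as m

system = m.assemble(m.default_model())
text = m.export_netlist(system)

lines = text.splitlines()
print("\n".join(lines[:12]))
print(f"...\n({len(lines)} lines: "
      f"{sum(l.startswith('C_') for l in lines)} capacitors, "
      f"{sum(l.startswith('R_') for l in lines)} resistors, "
      f"{sum(l.startswith('G') for l in lines)} controlled sources)")
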