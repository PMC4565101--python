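"""Proof of principle: needles inside the tumor electroporate all of it.

For a conductive tumor in low-conductivity fat, placing the needles inside
the tumor (almost tangent to its surface) instead of around it keeps the
current - and therefore the field - inside the target.  Pair voltages
follow the standard 1000 V/cm voltage-to-distance dosing rule applied to
the actual needle separations.
"""

from ectplan import (
    SigmaModel,
    SolverSettings,
    TissueModel,
    make_internal_config,
    protocol_for_config,
    rasterize,
    run_protocol,
    treated_fraction,
)

tissue = TissueModel()
for n in (5, 4):
    cfg = make_internal_config(tissue, n_electrodes=n)
    proto = protocol_for_config(cfg, voltage_to_distance=1000.0)
    grid = rasterize(tissue, cfg, spacing=0.15)
    cov = run_protocol(grid, proto, SigmaModel(), SolverSettings())
    rep = treated_fraction(cov, grid, 400.0)
    volts = ", ".join(f"{e.voltage:.0f}" for e in proto)
    print(f"{n} needles inside the tumor ({len(proto)} pairs at {volts} V):")
    print(f"  treated fraction at 400 V/cm: {rep.treated_fraction_pct:.1f} %\n")
print("Compare with ~13-24 % for the external placements: same dosing rule,")
print("near-complete electroporation once the needles sit inside the target.")
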