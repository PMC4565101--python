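"""Generate a synthetic pulse-generator log from a perturbed placement.

Draws a seeded placement perturbation (in-plane shifts of the external
needles, small tilts), forward-simulates every pair of the clinical
protocol, adds 5% multiplicative measurement noise, and prints the log in
the clinical CSV schema - the input the resistance analysis expects.
"""

from ectplan import (
    PerturbationSpec,
    SigmaModel,
    TissueModel,
    clinical_protocol,
    make_symmetric_config,
    perturb_config,
    resistance_from_log,
    simulate_log,
)

base = make_symmetric_config(TissueModel())
spec = PerturbationSpec(displacement_sd=2.0, tilt_sd=10.0, tilt_max=30.0, seed=7)
cfg = perturb_config(base, spec)
log = simulate_log(cfg, clinical_protocol(), SigmaModel(enabled=False),
                   noise_cv=0.05, seed=7, spacing_cm=0.15)

print(log.records.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
res = resistance_from_log(log.records)
central = res[res["probe_from"] == 5].set_index("probe_to")["resistance_ohm"]
dists = {eid: cfg.pair_distance(5, eid) for eid in (1, 2, 3, 4)}
print(f"\ntrue center distances (cm): " +
      ", ".join(f"{k}: {v:.2f}" for k, v in dists.items()))
farthest = max(dists, key=dists.get)
flagged = central.idxmax()
print(f"highest central-pair resistance: electrode {flagged} "
      f"(farthest-placed electrode: {farthest})")
if flagged == farthest:
    print("\nThe highest central-pair resistance identified the electrode that")
    print("drifted farthest out - the inference the resistance analysis relies on.")
else:
    print("\nHere the inference misses: with tilts, measurement noise and near-tied")
    print("distances the ranking can flip - it holds in >= 80 % of seeded draws,")
    print("not in every single one (see the parameter-recovery test).")
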