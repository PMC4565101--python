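"""Sensitivity of coverage and currents to the conductivity-step multipliers.

The two field thresholds (400 and 800 V/cm) are clinically standard, but
the factors by which electroporated tissue's conductivity rises are tissue-
dependent and poorly constrained.  This sweep shows how the treated-volume
fraction and the delivered currents respond across a plausible multiplier
range on the symmetric preset (1.5 mm grid for speed).

Coverage is only weakly (and non-monotonically) multiplier-dependent: a more
conductive electroporated halo carries more current but also flattens the
local field.  Delivered current, by contrast, scales strongly with the
multipliers - it is the observable that constrains them.
"""

from ectplan import (
    SigmaModel,
    SolverSettings,
    TissueModel,
    clinical_protocol,
    make_symmetric_config,
    rasterize,
    run_protocol,
    treated_fraction,
)

tissue = TissueModel()
grid = rasterize(tissue, make_symmetric_config(tissue), spacing=0.15)
print(f"{'f_rev':>6} {'f_irr':>6} {'treated %':>10} {'I(1-2) A':>9} {'I(5-1) A':>9}")
for f_rev, f_irr in ((1.0, 1.0), (1.5, 2.0), (2.5, 3.5), (3.0, 5.0), (3.0, 7.0)):
    cov = run_protocol(grid, clinical_protocol(),
                       SigmaModel(f_rev=f_rev, f_irr=f_irr), SolverSettings())
    rep = treated_fraction(cov, grid, 400.0)
    print(f"{f_rev:6.1f} {f_irr:6.1f} {rep.treated_fraction_pct:10.1f} "
          f"{cov.pair_currents[(1, 2)]:9.2f} {cov.pair_currents[(5, 1)]:9.2f}")
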