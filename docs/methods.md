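# Methods

## Physical model

The pulse trains used in electrochemotherapy (8 × 100 µs per pair) are long
compared to charge relaxation in tissue and short compared to thermal
diffusion, so each activation is modeled as a stationary conduction
problem: ∇·(σ∇V) = 0 with E = −∇V.  Dielectric, thermal, and transient
membrane-charging effects are out of scope.

Geometry is deliberately simple — a homogeneous fatty background box
(10 cm side, σ₀ = 0.04 S/m) containing a tumor ellipsoid (semi-axes
1.0 × 0.75 × 0.65 cm, σ₀ = 0.55 S/m) centered at the origin, and up to five
stainless-steel needles (σ = 4.032 × 10⁶ S/m) of which only the 3 cm active
segment conducts.  The coordinate convention puts the nominal insertion
axis along −z, the tumor mid-plane at z = 0 at the active-segment
mid-height (configurable offset), and slice maps are taken on z planes.

Membrane permeabilization raises bulk conductivity.  This is modeled as a
two-step function of the local field magnitude: σ = σ₀ below 400 V/cm
(reversible threshold), σ₀·f_rev in [400, 800) V/cm, σ₀·f_irr at or above
800 V/cm (irreversible threshold).  The thresholds are the standard
clinical values; the multipliers are tissue-dependent and poorly
constrained in the literature, so they are parameters (`SigmaModel`,
defaults f_rev = 2.5, f_irr = 3.5) and their influence is examined
explicitly (see Limitations).

Boundary conditions: the two active electrodes of a pair are equipotential
regions at the pulse amplitude and 0 V; inactive needles are floating
perfect conductors (equipotential, zero net current); five box faces are
insulating; one face (default −z, toward the chest wall) carries an
impedance condition J·n = (σ_b/L_ref)·V with σ_b = 0.5 S/m and reference
thickness L_ref = 5 cm, standing in for the conductive bulk of the body.
This face is a genuine current sink referenced to the generator ground, so
source and sink currents of a pair differ by the boundary leak; the
conservation identity I_src + I_snk + I_boundary = 0 holds to solver
tolerance and is asserted in the tests.  L_ref → ∞ recovers an insulated
box; the face and thickness are configurable.

## Discretization

Cell-centered voxels with odd counts per axis (so the tumor center and the
z = 0 plane are cell centers); default spacing 1 mm → 101³ cells.  Fluxes
use the 7-point stencil with harmonic-mean face conductivities, which
handles the ~14× tumor/fat conductivity jump without smearing.  Dirichlet
(active-electrode) voxels are eliminated into the right-hand side; each
floating needle is condensed into a single super-node unknown, which
enforces equipotentiality and zero net current exactly and keeps the
matrix well-conditioned (no 10⁷ conductivity contrast enters the system;
metal-adjacent faces still use the harmonic mean, i.e. effectively the
half-cell tissue resistance).

Two discretization details matter at clinically relevant resolutions:

- **Equivalent needle radius.**  A 0.6 mm needle rasterizes at 1 mm
  spacing to a one-voxel column, which behaves in the far field like a rod
  of radius 0.42 h (the logarithmic capacity of a square cross-section).
  Following well-block practice in reservoir simulation, the four lateral
  face conductances of every single-voxel needle slab are scaled by
  f = 1/(1 + (4/π) ln(0.42 h / a)).  Calibration is purely against the
  two-parallel-cylinder closed form R = acosh(d/2a)/(πσL): quasi-2D error
  after correction is below 1 % at both 1 mm and 2 mm spacing (≈ −10 %
  without it).  Slabs where the needle spans several voxels are left
  uncorrected.  The voxel-labeling radius is floored at half the in-plane
  voxel diagonal so tilted needles stay contiguous.

- **Material-aware gradients.**  |E| is evaluated at voxel centers by
  central differences, downgraded to one-sided differences at the grid
  boundary and wherever the neighbor belongs to the other tissue: the
  normal field jumps by the conductivity ratio at the tumor/fat interface,
  and differencing across it would spuriously electroporate a one-voxel
  tumor shell (a ~30 % volume artifact at 1 mm; with the one-sided scheme
  the shell statistics match the tumor interior).  Electrode voxels are
  equipotential and safe to difference against.

## Nonlinear iteration

Picard fixed point: solve the linear system, recompute |E|, reassign
threshold bands, update σ, repeat.  Two stabilizations:

- **Band latching** (default): a voxel that has crossed a threshold stays
  in the higher band.  This matches the sequential-permeabilization
  picture — during the pulse train, conductivity rise is not undone on the
  microsecond scale — and removes the limit cycle that a reversible step
  otherwise produces (≈ 1 % of voxels flickering around the 400 V/cm shell
  indefinitely).  With latching the iteration terminates, typically in 3–4
  steps; convergence is declared when fewer than 0.1 % of tissue voxels
  change band.  An unlatched mode with under-relaxation (`relax`) is
  available for sensitivity work.
- Each solution reports the conductivity actually used in its final linear
  solve, so potential, currents and σ are mutually consistent and charge
  conservation holds discretely.

Linear systems are solved by preconditioned conjugate gradients (Jacobi
for small grids; for ≥ 50 000 unknowns a symmetric two-level scheme:
damped-Jacobi smoothing around an exact Galerkin coarse solve on 5³-voxel
aggregates).  Default relative tolerance 10⁻⁸; warm starts across Picard
iterations.  A full 8-pair protocol at 1 mm runs in ≈ 2 minutes on one CPU.

## Protocol combination and metrics

Pairs are solved independently from baseline conductivity — matching the
sequential activations with max-combination of the resulting field maps —
and the coverage field is the voxelwise maximum of |E| (order-invariant;
an optional cumulative mode carries σ forward in protocol order for
sensitivity analysis).  The treated fraction counts whole tumor voxels
with coverage ≥ threshold (≥, not >; boundary voxels are measure-zero at
converged resolution), with per-slice area fractions at configurable z.
Pulse length and count are metadata: one stationary solve per pair.

Device-log analysis: R = V/I per pair, ranking, and extremes; the
measured-vs-computed table reports per-pair relative error against the
measured current.

## Electrode presets

- *symmetric*: externals at the corners of a 2 cm square (adjacent pairs
  2 cm, center-to-external √2 ≈ 1.4 cm), central needle at the origin, all
  vertical.  The square is inferred from the logged distance set
  {2, 2, 2, 2, 1.4 × 4}.
- *asymmetric*: externals 1–3 displaced 1.8/2.8/2.1 mm toward the center
  (the displacements are primary; the printed distances 1.22/1.12/1.19 cm
  agree to ~0.1 mm and are available as an alternative constructor), the
  central needle tilted 25° **about its entry point** — the physical pivot
  of a hand-inserted needle, and the reading under which the quoted
  center-to-external distances are unaffected by the tilt.  The tilt
  azimuth is not recorded clinically; the default leans into the upper
  (electrode 1–2) sector, which is the low-resistance side of the log and
  keeps clearance from both neighboring needles (tilting straight at
  electrode 2 would intersect its axis at depth).  Azimuth is
  configurable.
- *internal4/internal5*: needles on the tumor's mid-plane ellipse inset by
  one radius plus a configurable margin, at 90° spacing on the principal
  axes, optionally plus a central needle; pair voltages follow the
  1000 V/cm voltage-to-distance rule applied to the actual separations.

## Synthetic data

`perturb_config` models manual-insertion uncertainty: per-axis Gaussian
in-plane shifts of the external entry points (default SD 2 mm, the scale
of the clinically inferred displacements), half-normal tilts (default SD
10°, capped at 30°, uniform azimuth, entry-point pivot), seeded and
resampled on collision.  `simulate_log` forward-models the device log:
per-pair computed current with mean-preserving multiplicative lognormal
noise (default CV 5 % — devices of this class report currents to a few
percent), nominal distances rounded to 0.1 cm as the log prints them.
What the generator does **not** emulate: pulse-to-pulse current drift,
tissue heterogeneity beyond the two-compartment model, electrode-tissue
contact impedance, or deformation of the tissue by insertion — so passing
the recovery tests shows the inference logic is sound under the model's
own assumptions, not that it is robust to everything a clinic produces.

## Verification

- Two-parallel-cylinder closed form within 10 % (quasi-2D, uniform box).
- Charge conservation ≤ 10⁻³ per solve; exact V↔I linearity with the
  step model disabled; reciprocity under source/sink swap; enabling
  electroporation never decreases delivered current.
- Tumor voxel volume converges to the analytic ellipsoid volume;
  pair currents change ≤ 5 % under spacing halving (0.25 → 0.125 cm).
- Treated fraction monotone in threshold and in overall voltage scale;
  max-combination order-invariant and dominating.
- Placement-inference property: over 10 seeded perturbations, the
  external needle farthest from the center has the highest central-pair
  resistance in ≥ 80 % of runs (at 1.5 mm spacing; coarser grids let voxel
  quantization swamp millimeter shifts).

## Numerical and design choices, limitations

- Production spacing is 1 mm (101³; 16 nonlinear solves in ≈ 4 minutes).
  Refining to 0.75 mm raises pair currents by ~2–5 % and treated fractions
  by ~1–2 points — the reported figures are slightly conservative.
- The treated fraction counts whole voxels; no sub-voxel interpolation.
- The σ(E) multipliers dominate the delivered-current scale: on the
  symmetric preset the external-pair current roughly doubles between
  (f_rev, f_irr) = (1.5, 2.0) and (3.0, 7.0), while the treated fraction
  moves only a few points and non-monotonically (a more conductive halo
  carries more current but flattens the local field).  With the defaults
  (2.5, 3.5) computed central-pair currents agree with the device readings
  to a few percent, while external-pair currents are ~20–25 % low —
  consistent with electroporated fat rising more steeply than the uniform
  default multiplier assumes.  `examples/multiplier_sensitivity.py`
  reproduces this sweep.
- The impedance-face thickness L_ref = 5 cm is a modeling choice, not a
  measured quantity; it noticeably affects central-pair currents (the
  body-return path) and is exposed in `SolverSettings`.
- No patient imaging, curved or deformable needles, pulse-train dynamics,
  Joule heating, or frequency-dependent impedance.
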