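"""Stationary current-conduction solver with field-dependent conductivity.

The potential satisfies div(sigma grad V) = 0 on a cell-centered structured
grid (7-point finite-volume stencil, harmonic-mean face conductivities).
Both active electrodes of a pair are Dirichlet regions (source at the pulse
amplitude, sink grounded); inactive electrodes are floating perfect
conductors, each condensed into a single equipotential unknown with zero net
current.  Five box faces are insulating; one face carries an impedance
(Robin) condition standing in for the surrounding body.

Electroporation enters through a step increase of tissue conductivity with
the local field magnitude: baseline below the reversible threshold, times
``f_rev`` between the reversible and irreversible thresholds, times
``f_irr`` above.  The nonlinearity is resolved by Picard iteration with
under-relaxation on sigma; convergence is declared when the fraction of
tissue voxels switching threshold band drops below ``band_tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import CM, ELECTRODE_BASE, LabeledGrid

V_PER_CM = 1.0 / CM  # V/m per V/cm

_FACES = {"-x": (0, 0), "+x": (0, -1), "-y": (1, 0), "+y": (1, -1), "-z": (2, 0), "+z": (2, -1)}


@dataclass(frozen=True)
class SigmaModel:
    """Step model of conductivity rise with local field magnitude.

    Thresholds are in V/cm (clinical convention).  ``f_rev`` and ``f_irr``
    multiply the baseline conductivity of tissue voxels in the reversible
    band [E_rev, E_irr) and the irreversible band [E_irr, inf).
    """

    E_rev: float = 400.0
    E_irr: float = 800.0
    f_rev: float = 2.5
    f_irr: float = 3.5
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.E_rev < self.E_irr):
            raise ValueError("thresholds must satisfy 0 < E_rev < E_irr")
        if not (1.0 <= self.f_rev <= self.f_irr):
            raise ValueError("multipliers must satisfy 1 <= f_rev <= f_irr")

    def multipliers(self, field_v_per_cm: np.ndarray) -> np.ndarray:
        """Per-voxel conductivity multiplier for a field magnitude in V/cm."""
        if not self.enabled:
            return np.ones_like(field_v_per_cm)
        out = np.ones_like(field_v_per_cm)
        out[field_v_per_cm >= self.E_rev] = self.f_rev
        out[field_v_per_cm >= self.E_irr] = self.f_irr
        return out

    def bands(self, field_v_per_cm: np.ndarray) -> np.ndarray:
        """0 below E_rev, 1 in the reversible band, 2 at or above E_irr."""
        return (field_v_per_cm >= self.E_rev).astype(np.int8) + (
            field_v_per_cm >= self.E_irr
        ).astype(np.int8)


@dataclass(frozen=True)
class PairExcitation:
    """One activated electrode pair: source held at ``voltage``, sink grounded."""

    source_id: int
    sink_id: int
    voltage: float

    def __post_init__(self) -> None:
        if self.source_id == self.sink_id:
            raise ValueError("source and sink must differ")
        if self.voltage < 0:
            raise ValueError("voltage must be non-negative")


@dataclass(frozen=True)
class SolverSettings:
    """Numerical knobs for one nonlinear solve.

    ``robin_face`` selects which box face carries the impedance condition
    J.n = (sigma_boundary / L_ref) * V; ``robin_L_ref`` is the reference
    thickness in cm (insulating in the limit L_ref -> inf).
    """

    band_tol: float = 1e-3        # fraction of tissue voxels changing band
    max_iter: int = 40
    relax: float = 1.0            # under-relaxation on sigma
    latch_bands: bool = True      # permeabilized voxels stay permeabilized
    cg_rtol: float = 1e-8
    cg_maxiter: int = 5000
    robin_face: Optional[str] = "-z"
    robin_L_ref: float = 5.0      # cm
    electrode_radius_correction: bool = True
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.robin_face is not None and self.robin_face not in _FACES:
            raise ValueError(f"robin_face must be one of {sorted(_FACES)} or None")
        if not (0 < self.relax <= 1):
            raise ValueError("relax must be in (0, 1]")


@dataclass
class FieldSolution:
    """Converged (or flagged) solution for one electrode pair."""

    excitation: PairExcitation
    potential: np.ndarray          # V, full grid
    field_magnitude: np.ndarray    # V/cm
    sigma_final: np.ndarray        # S/m
    currents: dict[int, float]     # signed A per electrode (source > 0)
    boundary_flux: float           # A entering through the impedance face (<= 0 when leaking out)
    iterations: int
    residual: float                # final band-change fraction
    converged: bool
    floating_potentials: dict[int, float] = field(default_factory=dict)
    convergence_log: list[dict] = field(default_factory=list, repr=False)

    @property
    def conservation_error(self) -> float:
        """|I_source + I_sink + I_robin| / |I_source| (charge balance)."""
        i_src = self.currents[self.excitation.source_id]
        i_snk = self.currents[self.excitation.sink_id]
        if i_src == 0.0:
            return 0.0
        return abs(i_src + i_snk + self.boundary_flux) / abs(i_src)


#: far-field equivalent rod radius of a one-voxel Dirichlet column, in units
#: of the voxel edge (logarithmic capacity of a square cross-section;
#: confirmed numerically against the two-cylinder closed form)
_SQUARE_ROD_RADIUS = 0.42


def _radius_correction_multipliers(grid: LabeledGrid):
    """Per-face conductance multipliers realizing the physical needle radius.

    A needle thinner than a voxel rasterizes to a one-voxel column whose
    far-field behavior is a rod of radius ~0.42 h, not the physical radius
    ``a``.  Following well-block practice, the four lateral face
    conductances of each single-voxel cross-section are scaled by
    f = 1 / (1 + (4/pi) ln(r_eq / a)), which adds the missing annular
    resistance (or removes the excess) between the two radii.  Slabs where
    the needle occupies several voxels already resolve the radius and are
    left untouched.
    """
    if grid.config is None:
        return None
    hx, hy, hz = grid.spacing
    r_eq = _SQUARE_ROD_RADIUS * np.sqrt(hx * hy)
    shape = grid.shape
    mx = np.ones((shape[0] - 1, shape[1], shape[2]))
    my = np.ones((shape[0], shape[1] - 1, shape[2]))
    mz = np.ones((shape[0], shape[1], shape[2] - 1))
    any_corrected = False
    for e in grid.config:
        a = e.radius * 1e-3  # mm -> m
        inv_f = 1.0 + (4.0 / np.pi) * np.log(r_eq / a)
        f = 1.0 / np.clip(inv_f, 0.15, 4.0)
        if abs(f - 1.0) < 1e-3:
            continue
        mask = grid.electrode_mask(e.id)
        per_slab = mask.sum(axis=(0, 1))
        for k in np.nonzero(per_slab == 1)[0]:
            i, j = (int(v[0]) for v in np.nonzero(mask[:, :, k]))
            any_corrected = True
            if i > 0:
                mx[i - 1, j, k] *= f
            if i < shape[0] - 1:
                mx[i, j, k] *= f
            if j > 0:
                my[i, j - 1, k] *= f
            if j < shape[1] - 1:
                my[i, j, k] *= f
    if not any_corrected:
        return None
    return (mx, my, mz)


class _TwoLevelPreconditioner:
    """Symmetric V(1,1) two-grid preconditioner for the conduction system.

    Damped-Jacobi smoothing around an exact solve of the Galerkin coarse
    operator built from 3x3x3 voxel aggregates; floating-electrode
    super-nodes keep their own aggregate.  SPD, so safe inside CG.
    """

    def __init__(self, system: "AssembledSystem", coarsen: int = 5, omega: float = 0.7):
        self.omega = omega
        grid = system.grid
        free = grid.label < ELECTRODE_BASE
        ii, jj, kk = np.nonzero(free)  # same C-order as the unknown numbering
        ncy = -(-grid.shape[1] // coarsen)
        ncz = -(-grid.shape[2] // coarsen)
        agg = (ii // coarsen) * ncy * ncz + (jj // coarsen) * ncz + (kk // coarsen)
        extra = np.arange(len(system.floating_ids)) + (agg.max() + 1 if agg.size else 0)
        agg = np.concatenate([agg, extra])
        _, inv = np.unique(agg, return_inverse=True)
        n, nc = system.n_unknowns, int(inv.max()) + 1
        self.P = sp.csr_matrix((np.ones(n), (np.arange(n), inv)), shape=(n, nc))
        self.Pt = self.P.T.tocsr()
        self.A = None
        self._lu = None

    def update(self, A: sp.csr_matrix) -> None:
        self.A = A
        self.diag = A.diagonal()
        Ac = (self.Pt @ A @ self.P).tocsc()
        self._lu = spla.splu(Ac)

    def apply(self, r: np.ndarray) -> np.ndarray:
        x = self.omega * r / self.diag
        rr = r - self.A @ x
        x = x + self.P @ self._lu.solve(self.Pt @ rr)
        rr = r - self.A @ x
        return x + self.omega * rr / self.diag

    def as_operator(self) -> spla.LinearOperator:
        return spla.LinearOperator(self.A.shape, matvec=self.apply)


class AssembledSystem:
    """Sparse linear system for one pair on one grid.

    The sparsity structure and the unknown numbering depend only on the grid
    and the excitation, so they are built once and reused across Picard
    iterations; only the conductance data changes with sigma.
    """

    def __init__(self, grid: LabeledGrid, excitation: PairExcitation, settings: SolverSettings):
        self.grid = grid
        self.excitation = excitation
        self.settings = settings
        label = grid.label
        eids = grid.electrode_ids
        for eid in (excitation.source_id, excitation.sink_id):
            if eid not in eids:
                raise ValueError(f"electrode {eid} not present in grid")

        # unknown numbering: tissue voxels first, then one super-node per
        # floating electrode; active-electrode voxels are Dirichlet (-1)
        free = label < ELECTRODE_BASE
        self.n_tissue = int(free.sum())
        u = np.full(grid.shape, -1, dtype=np.int64)
        u[free] = np.arange(self.n_tissue)
        self.floating_ids = [
            eid for eid in eids if eid not in (excitation.source_id, excitation.sink_id)
        ]
        for k, eid in enumerate(self.floating_ids):
            u[grid.electrode_mask(eid)] = self.n_tissue + k
        self.n_unknowns = self.n_tissue + len(self.floating_ids)
        self.dirichlet_value = np.zeros(grid.shape)
        self.dirichlet_value[grid.electrode_mask(excitation.source_id)] = excitation.voltage
        self.unknown_index = u
        if self.n_unknowns == 0:
            raise ValueError("no unknowns: grid is entirely Dirichlet")

        # face lists per axis: flat indices of the low/high cell of each face
        nx, ny, nz = grid.shape
        flat = np.arange(nx * ny * nz).reshape(grid.shape)
        gmult = _radius_correction_multipliers(grid) if settings.electrode_radius_correction else None
        self._faces = []
        uf = u.ravel()
        for ax in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(0, -1)
            sl_hi[ax] = slice(1, None)
            p = flat[tuple(sl_lo)].ravel()
            q = flat[tuple(sl_hi)].ravel()
            up, uq = uf[p], uf[q]
            keep = ~((up == uq) & (up >= 0))  # drop intra-super-node faces
            keep &= ~((up < 0) & (uq < 0))    # drop Dirichlet-Dirichlet faces
            mult = gmult[ax].ravel()[keep] if gmult is not None else None
            self._faces.append((p[keep], q[keep], up[keep], uq[keep], mult))

        # impedance face: conductance per boundary voxel to ground
        self._robin_flat = np.empty(0, dtype=np.int64)
        self.robin_g = 0.0
        if settings.robin_face is not None:
            ax, side = _FACES[settings.robin_face]
            sl = [slice(None)] * 3
            sl[ax] = side
            self._robin_flat = flat[tuple(sl)].ravel()
            area = grid.voxel_volume / grid.spacing[ax]
            sigma_b = grid.tissue.sigma_boundary if grid.tissue is not None else 0.5
            self.robin_g = sigma_b / (settings.robin_L_ref * CM) * area
        if self.n_tissue == self.n_unknowns and not np.any(self.dirichlet_value) \
                and excitation.voltage == 0 and self.robin_g == 0.0:
            raise ValueError("singular system: no Dirichlet voxels and no impedance face")

    def face_conductances(self, sigma: np.ndarray) -> list[np.ndarray]:
        """Harmonic-mean conductance g = A/h * 2*s1*s2/(s1+s2) per interior face.

        Faces flagged by the equivalent-radius correction carry an extra
        geometric multiplier so a one-voxel needle column realizes the
        physical electrode radius rather than the voxel's own.
        """
        out = []
        h = self.grid.spacing
        vol = self.grid.voxel_volume
        sf = sigma.ravel()
        for ax, (p, q, _, _, mult) in enumerate(self._faces):
            s1, s2 = sf[p], sf[q]
            g = (vol / h[ax] ** 2) * 2.0 * s1 * s2 / (s1 + s2)
            if mult is not None:
                g = g * mult
            out.append(g)
        return out

    def build(self, sigma: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray]:
        """Assemble the SPD system A x = b for the given conductivity field."""
        n = self.n_unknowns
        rows, cols, data = [], [], []
        b = np.zeros(n)
        dvf = self.dirichlet_value.ravel()
        for (p, q, up, uq, _), g in zip(self._faces, self.face_conductances(sigma)):
            both = (up >= 0) & (uq >= 0)
            rows += [up[both], uq[both], up[both], uq[both]]
            cols += [up[both], uq[both], uq[both], up[both]]
            data += [g[both], g[both], -g[both], -g[both]]
            for u_free, f_fixed in ((up, q), (uq, p)):
                m = (u_free >= 0) & ~both
                rows.append(u_free[m])
                cols.append(u_free[m])
                data.append(g[m])
                b += np.bincount(u_free[m], weights=g[m] * dvf[f_fixed[m]], minlength=n)
        if self._robin_flat.size:
            ur = self.unknown_index.ravel()[self._robin_flat]
            m = ur >= 0
            rows.append(ur[m])
            cols.append(ur[m])
            data.append(np.full(int(m.sum()), self.robin_g))
        A = sp.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
        )
        return A, b

    def expand(self, x: np.ndarray) -> np.ndarray:
        """Scatter the unknown vector back to a full potential array."""
        V = self.dirichlet_value.copy()
        u = self.unknown_index
        m = u >= 0
        V[m] = x[u[m]]
        return V

    def electrode_current(self, electrode_id: int, V: np.ndarray, g_faces) -> float:
        """Net conduction current leaving an electrode (A)."""
        mask = self.grid.electrode_mask(electrode_id).ravel()
        Vf = V.ravel()
        total = 0.0
        for (p, q, _, _, _), g in zip(self._faces, g_faces):
            m = mask[p] & ~mask[q]
            total += float(np.sum(g[m] * (Vf[p[m]] - Vf[q[m]])))
            m = mask[q] & ~mask[p]
            total += float(np.sum(g[m] * (Vf[q[m]] - Vf[p[m]])))
        if self._robin_flat.size:
            m = mask[self._robin_flat]
            total += float(self.robin_g * np.sum(Vf[self._robin_flat[m]]))
        return total

    def robin_flux(self, V: np.ndarray) -> float:
        """Current leaving the domain through the impedance face (A)."""
        if not self._robin_flat.size:
            return 0.0
        return float(self.robin_g * np.sum(V.ravel()[self._robin_flat]))


def assemble_system(
    grid: LabeledGrid,
    sigma: np.ndarray,
    excitation: PairExcitation,
    settings: SolverSettings | None = None,
) -> tuple[sp.csr_matrix, np.ndarray, AssembledSystem]:
    """Build the linear system for one conductivity field (single Picard step)."""
    settings = settings or SolverSettings()
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive everywhere")
    system = AssembledSystem(grid, excitation, settings)
    A, b = system.build(sigma)
    return A, b, system


def field_magnitude(V: np.ndarray, grid: LabeledGrid) -> np.ndarray:
    """|E| = |grad V| at voxel centers, in V/cm.

    Central differences in the interior, one-sided at the grid boundary and
    across tissue-material interfaces.  The normal field component jumps by
    the conductivity ratio at the tumor/background boundary (~14x here);
    differencing across that jump would smear the high outside field into a
    one-voxel shell of tumor and corrupt every coverage statistic, so cells
    bordering the other tissue use the difference on their own side.
    Electrode voxels are equipotential and safe to difference against.
    """
    h = grid.spacing
    mat = np.where(grid.label >= ELECTRODE_BASE, -1, grid.label).astype(np.int8)
    out = np.zeros(grid.shape)
    for ax in range(3):
        Vf = np.moveaxis(V, ax, 0)
        m = np.moveaxis(mat, ax, 0)
        g = np.empty_like(Vf)
        # central difference everywhere it is defined
        g[1:-1] = (Vf[2:] - Vf[:-2]) / (2 * h[ax])
        g[0] = (Vf[1] - Vf[0]) / h[ax]
        g[-1] = (Vf[-1] - Vf[-2]) / h[ax]
        # material-aware downgrades to one-sided differences (interior only);
        # electrode cells (-1) match any tissue
        same_lo = (m[1:-1] == m[:-2]) | (m[:-2] == -1) | (m[1:-1] == -1)
        same_hi = (m[1:-1] == m[2:]) | (m[2:] == -1) | (m[1:-1] == -1)
        fwd = (Vf[2:] - Vf[1:-1]) / h[ax]
        bwd = (Vf[1:-1] - Vf[:-2]) / h[ax]
        g[1:-1] = np.where(same_hi & ~same_lo, fwd, g[1:-1])
        g[1:-1] = np.where(same_lo & ~same_hi, bwd, g[1:-1])
        out += np.moveaxis(g, 0, ax) ** 2
    return np.sqrt(out) / V_PER_CM


def sigma_update(
    field_v_per_cm: np.ndarray,
    grid: LabeledGrid,
    sigma_model: SigmaModel,
) -> np.ndarray:
    """Target conductivity for a given field map (no relaxation applied).

    Tissue voxels get baseline sigma times the band multiplier; electrode
    voxels keep their metal conductivity.  Idempotent for a fixed field.
    """
    mult = sigma_model.multipliers(field_v_per_cm)
    mult[grid.label >= ELECTRODE_BASE] = 1.0
    return grid.baseline_sigma * mult


def _cg_solve(A, b, x0, settings: SolverSettings, M=None) -> tuple[np.ndarray, int]:
    diag = A.diagonal()
    if np.any(diag <= 0):
        raise RuntimeError("singular system: non-positive diagonal after assembly")
    if M is None:
        M = spla.LinearOperator(A.shape, matvec=lambda v: v / diag)
    count = [0]

    def _cb(_):
        count[0] += 1

    x, info = spla.cg(A, b, x0=x0, rtol=settings.cg_rtol, atol=0.0,
                      maxiter=settings.cg_maxiter, M=M, callback=_cb)
    if info > 0:
        x, info = spla.cg(A, b, x0=x, rtol=settings.cg_rtol * 10, atol=0.0,
                          maxiter=settings.cg_maxiter, M=M, callback=_cb)
        if info > 0:
            raise RuntimeError(f"conjugate-gradient solver did not converge (info={info})")
    if info < 0:
        raise RuntimeError("conjugate-gradient solver breakdown")
    return x, count[0]


def solve_pair(
    grid: LabeledGrid,
    excitation: PairExcitation,
    sigma_model: SigmaModel | None = None,
    settings: SolverSettings | None = None,
) -> FieldSolution:
    """Solve one electrode pair with the field-dependent conductivity model.

    Picard loop: solve the linear conduction problem, recompute |E|, update
    sigma through the step rule with under-relaxation, repeat until the
    fraction of tissue voxels changing threshold band falls below
    ``settings.band_tol`` (or ``max_iter`` is hit, in which case the solution
    is returned flagged as unconverged).
    """
    sigma_model = sigma_model or SigmaModel()
    settings = settings or SolverSettings()
    system = AssembledSystem(grid, excitation, settings)

    sigma = grid.baseline_sigma.copy()
    tissue_mask = grid.label < ELECTRODE_BASE
    n_tissue = max(int(tissue_mask.sum()), 1)
    bands = np.zeros(grid.shape, dtype=np.int8)
    x = None
    iterations = 0
    change = 1.0
    converged = False
    emag = np.zeros(grid.shape)

    if excitation.voltage == 0.0:
        # homogeneous data: potential identically zero
        V = np.zeros(grid.shape)
        currents = {eid: 0.0 for eid in grid.electrode_ids}
        return FieldSolution(excitation, V, emag, sigma, currents, 0.0, 0, 0.0, True,
                             {eid: 0.0 for eid in system.floating_ids})

    max_iter = settings.max_iter if sigma_model.enabled else 1
    sigma_used = sigma
    V = np.zeros(grid.shape)
    log: list[dict] = []
    precond = _TwoLevelPreconditioner(system) if system.n_unknowns >= 50_000 else None
    mult_of_band = np.array([1.0, sigma_model.f_rev, sigma_model.f_irr])
    for iterations in range(1, max_iter + 1):
        A, b = system.build(sigma)
        sigma_used = sigma  # conductivity consistent with this potential
        M = None
        if precond is not None:
            # refresh the coarse factorization only when sigma drifted enough
            # to degrade it (CG count creeping up)
            if precond.A is None or log and log[-1]["cg_iterations"] > 60:
                precond.update(A)
            else:
                precond.A = A
                precond.diag = A.diagonal()
            M = precond.as_operator()
        x, n_cg = _cg_solve(A, b, x, settings, M=M)
        V = system.expand(x)
        emag = field_magnitude(V, grid)
        new_bands = sigma_model.bands(emag)
        new_bands[~tissue_mask] = 0
        if settings.latch_bands:
            np.maximum(new_bands, bands, out=new_bands)
        change = float(np.count_nonzero(new_bands != bands)) / n_tissue
        bands = new_bands
        log.append({"iteration": iterations, "cg_iterations": n_cg,
                    "band_change_fraction": change})
        if settings.verbose:
            print(f"    picard {iterations}: cg={n_cg} band_change={change:.2e}", flush=True)
        if not sigma_model.enabled:
            converged = True
            break
        target = grid.baseline_sigma * np.where(tissue_mask, mult_of_band[bands], 1.0)
        if change <= settings.band_tol and (iterations >= 2 or np.allclose(sigma, target)):
            converged = True
            break
        sigma = sigma + settings.relax * (target - sigma)

    g_faces = system.face_conductances(sigma_used)
    currents = {eid: system.electrode_current(eid, V, g_faces) for eid in grid.electrode_ids}
    floating = {}
    for k, eid in enumerate(system.floating_ids):
        floating[eid] = float(x[system.n_tissue + k])
    return FieldSolution(
        excitation=excitation,
        potential=V,
        field_magnitude=emag,
        sigma_final=sigma_used.copy(),
        currents=currents,
        boundary_flux=-system.robin_flux(V),
        iterations=iterations,
        residual=change,
        converged=converged,
        floating_potentials=floating,
        convergence_log=log,
    )


def compute_current(solution: FieldSolution, grid: LabeledGrid, electrode_id: int,
                    settings: SolverSettings | None = None) -> float:
    """Signed current for one electrode from a stored solution (A)."""
    settings = settings or SolverSettings()
    system = AssembledSystem(grid, solution.excitation, settings)
    g_faces = system.face_conductances(solution.sigma_final)
    return system.electrode_current(electrode_id, solution.potential, g_faces)
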