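"""Simulation geometry: tissue model, needle electrodes, and voxelization.

The treated anatomy is reduced to a homogeneous low-conductivity background
box (fatty breast tissue) containing a conductive tumor ellipsoid.  Five
single-needle electrodes are inserted through the tumor region; only the
exposed active segment of each needle is modeled.  All user-facing lengths
are centimeters except the electrode radius (millimeters), matching how the
quantities are logged clinically; the voxel grid and the solver work in SI
units (meters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

CM = 1e-2  # meters per centimeter
MM = 1e-3  # meters per millimeter

#: voxel label values (electrode voxels are ELECTRODE_BASE + electrode id)
BACKGROUND = 0
TUMOR = 1
ELECTRODE_BASE = 100


@dataclass(frozen=True)
class TissueModel:
    """Background box plus tumor ellipsoid with baseline conductivities.

    Parameters
    ----------
    box_side : float
        Side of the cubic simulation domain, cm.
    tumor_center : tuple of float
        Center of the tumor ellipsoid, cm (also the grid origin).
    tumor_semiaxes : tuple of float
        Ellipsoid semi-axes, cm.  Defaults correspond to a nodule with
        principal axes 2 cm x 1.5 cm and thickness 1.3 cm.
    sigma_tumor0, sigma_background0 : float
        Baseline (non-electroporated) conductivities, S/m.
    sigma_boundary : float
        Conductivity used by the impedance (Robin) face standing in for the
        rest of the body, S/m.
    """

    box_side: float = 10.0
    tumor_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tumor_semiaxes: tuple[float, float, float] = (1.0, 0.75, 0.65)
    sigma_tumor0: float = 0.55
    sigma_background0: float = 0.04
    sigma_boundary: float = 0.5

    def __post_init__(self) -> None:
        ax = np.asarray(self.tumor_semiaxes, float)
        if np.any(ax <= 0):
            raise ValueError("tumor semiaxes must be positive")
        if self.sigma_tumor0 <= 0 or self.sigma_background0 <= 0 or self.sigma_boundary <= 0:
            raise ValueError("conductivities must be positive")
        c = np.asarray(self.tumor_center, float)
        if np.any(np.abs(c) + ax > self.box_side / 2):
            raise ValueError("tumor ellipsoid must lie fully inside the box")

    @property
    def tumor_volume_cm3(self) -> float:
        """Analytic ellipsoid volume, cm^3."""
        a, b, c = self.tumor_semiaxes
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class NeedleElectrode:
    """One single-needle electrode (active segment only).

    ``entry_point`` is the top of the active segment (cm); ``direction`` is
    the unit insertion vector; the active segment runs from the entry point
    to ``entry_point + active_length * direction``.
    """

    id: int
    entry_point: tuple[float, float, float]
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    active_length: float = 3.0     # cm
    radius: float = 0.6            # mm
    sigma: float = 4.032e6         # S/m, stainless steel

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError(f"electrode {self.id}: direction must be a unit vector")
        if self.active_length <= 0 or self.radius <= 0:
            raise ValueError(f"electrode {self.id}: active_length and radius must be positive")

    @property
    def tip(self) -> np.ndarray:
        """Deep end of the active segment, cm."""
        return np.asarray(self.entry_point, float) + self.active_length * np.asarray(self.direction, float)

    @property
    def midpoint(self) -> np.ndarray:
        """Mid-height of the active segment, cm."""
        return np.asarray(self.entry_point, float) + 0.5 * self.active_length * np.asarray(self.direction, float)

    def point_at_z(self, z: float) -> np.ndarray:
        """Point on the (extended) axis at height ``z`` (cm)."""
        p = np.asarray(self.entry_point, float)
        d = np.asarray(self.direction, float)
        if abs(d[2]) < 1e-12:
            raise ValueError("electrode axis is horizontal; no unique point at fixed z")
        t = (z - p[2]) / d[2]
        return p + t * d


@dataclass(frozen=True)
class ElectrodeConfig:
    """An ordered set of needle electrodes with a human-readable label."""

    electrodes: tuple[NeedleElectrode, ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        ids = [e.id for e in self.electrodes]
        if len(set(ids)) != len(ids):
            raise ValueError("electrode ids must be unique")
        for i, a in enumerate(self.electrodes):
            for b in self.electrodes[i + 1:]:
                dmin = _segment_distance(
                    np.asarray(a.entry_point), a.tip, np.asarray(b.entry_point), b.tip
                )
                if dmin < (a.radius + b.radius) * MM / CM:
                    raise ValueError(f"electrodes {a.id} and {b.id} overlap")

    def __iter__(self):
        return iter(self.electrodes)

    def __len__(self) -> int:
        return len(self.electrodes)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(e.id for e in self.electrodes)

    def get(self, electrode_id: int) -> NeedleElectrode:
        for e in self.electrodes:
            if e.id == electrode_id:
                return e
        raise KeyError(f"no electrode with id {electrode_id}")

    def pair_distance(self, id_a: int, id_b: int, z: float | None = None) -> float:
        """Lateral distance (cm) between two electrodes.

        By default the nominal placement distance (between entry points, the
        quantity a device log records); pass ``z`` to probe the axis-to-axis
        distance at a given height, which differs for tilted needles.
        """
        if z is None:
            pa = np.asarray(self.get(id_a).entry_point, float)
            pb = np.asarray(self.get(id_b).entry_point, float)
        else:
            pa = self.get(id_a).point_at_z(z)
            pb = self.get(id_b).point_at_z(z)
        return float(np.linalg.norm((pa - pb)[:2]))


def _segment_distance(p1: np.ndarray, p2: np.ndarray, q1: np.ndarray, q2: np.ndarray) -> float:
    """Minimum distance between two 3D segments."""
    u = p2 - p1
    v = q2 - q1
    w = p1 - q1
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-14:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-14 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # re-clamp s for the clamped t
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-14 else 0.0
    return float(np.linalg.norm(p1 + s * u - (q1 + t * v)))


# ---------------------------------------------------------------------------
# preset configurations
# ---------------------------------------------------------------------------

# externals sit at the corners of a square, numbered consecutively around it
# so that pairs (1,2),(2,3),(3,4),(4,1) are the square's sides
_SQUARE_CORNERS = {
    1: (+1.0, +1.0),
    2: (-1.0, +1.0),
    3: (-1.0, -1.0),
    4: (+1.0, -1.0),
}

CENTRAL_ID = 5


def make_symmetric_config(
    tissue: TissueModel | None = None,
    side: float = 2.0,
    active_length: float = 3.0,
    radius: float = 0.6,
    z_offset: float = 0.0,
) -> ElectrodeConfig:
    """Nominal five-electrode layout: four externals on a square of side
    ``side`` (cm) around the tumor plus one central electrode, all parallel
    to z.  The tumor mid-plane sits at the active-segment mid-height, shifted
    by ``z_offset`` (cm).
    """
    tissue = tissue or TissueModel()
    cx, cy, cz = tissue.tumor_center
    top = cz + active_length / 2 + z_offset
    electrodes = []
    for eid, (ux, uy) in _SQUARE_CORNERS.items():
        electrodes.append(
            NeedleElectrode(
                id=eid,
                entry_point=(cx + ux * side / 2, cy + uy * side / 2, top),
                active_length=active_length,
                radius=radius,
            )
        )
    electrodes.append(
        NeedleElectrode(
            id=CENTRAL_ID,
            entry_point=(cx, cy, top),
            active_length=active_length,
            radius=radius,
        )
    )
    return ElectrodeConfig(tuple(electrodes), label="symmetric")


def make_asymmetric_config(
    tissue: TissueModel | None = None,
    displacements_mm: dict[int, float] | None = None,
    tilt_deg: float = 25.0,
    tilt_azimuth_deg: float | None = None,
    **kwargs,
) -> ElectrodeConfig:
    """Perturbed layout reconstructing the uncertain manual insertion.

    External electrodes 1-3 are moved toward the central electrode along the
    line joining each to the center (defaults 1.8, 2.8, 2.1 mm); electrode 4
    is unchanged; the central electrode is tilted ``tilt_deg`` from vertical,
    pivoting about its entry point (the way an inserted needle actually
    leans), so its deep half sweeps sideways across the tumor.
    ``tilt_azimuth_deg`` sets the horizontal direction of the tilt (degrees
    from +x, counterclockwise); the default (90, toward the electrode 1-2
    side) leans the needle into the low-resistance upper sector while
    keeping clearance from both neighboring needles -- tilting straight at
    electrode 2 would make the axes collide at depth.
    """
    tissue = tissue or TissueModel()
    if displacements_mm is None:
        displacements_mm = {1: 1.8, 2: 2.8, 3: 2.1}
    base = make_symmetric_config(tissue, **kwargs)
    center = np.asarray(tissue.tumor_center, float)
    electrodes = []
    for e in base:
        if e.id in displacements_mm and e.id != CENTRAL_ID:
            entry = np.asarray(e.entry_point, float)
            radial = entry[:2] - center[:2]
            dist = np.linalg.norm(radial)
            shift = displacements_mm[e.id] * MM / CM
            if shift >= dist:
                raise ValueError(
                    f"displacement {displacements_mm[e.id]} mm moves electrode {e.id} past the center"
                )
            if shift != 0.0:
                entry = entry.copy()
                entry[:2] -= shift * radial / dist
                e = replace(e, entry_point=tuple(entry))
        elif e.id == CENTRAL_ID and tilt_deg != 0.0:
            azimuth = np.deg2rad(90.0 if tilt_azimuth_deg is None else tilt_azimuth_deg)
            theta = np.deg2rad(tilt_deg)
            direction = np.array(
                [np.sin(theta) * np.cos(azimuth), np.sin(theta) * np.sin(azimuth), -np.cos(theta)]
            )
            e = replace(e, direction=tuple(direction))
        electrodes.append(e)
    return ElectrodeConfig(tuple(electrodes), label="asymmetric")


def make_asymmetric_config_from_distances(
    tissue: TissueModel | None = None,
    center_distances_cm: dict[int, float] | None = None,
    **kwargs,
) -> ElectrodeConfig:
    """Alternative entry path: specify the perturbed center-to-external
    distances directly (defaults 1.22, 1.12, 1.19 cm for electrodes 1-3).
    """
    tissue = tissue or TissueModel()
    if center_distances_cm is None:
        center_distances_cm = {1: 1.22, 2: 1.12, 3: 1.19}
    base = make_symmetric_config(tissue)
    center = np.asarray(tissue.tumor_center, float)
    displacements = {}
    for eid, target in center_distances_cm.items():
        entry = np.asarray(base.get(eid).entry_point, float)
        current = float(np.linalg.norm(entry[:2] - center[:2]))
        displacements[eid] = (current - target) / MM * CM
    return replace(
        make_asymmetric_config(tissue, displacements_mm=displacements, **kwargs),
        label="asymmetric",
    )


def make_internal_config(
    tissue: TissueModel | None = None,
    n_electrodes: int = 5,
    margin: float = 0.0,
    active_length: float = 3.0,
    radius: float = 0.6,
    z_offset: float = 0.0,
) -> ElectrodeConfig:
    """Electrodes placed inside the tumor, almost tangent to its surface.

    Four electrodes sit on the tumor's mid-plane ellipse inset by
    ``margin + radius`` from the surface, at 90-degree angular spacing on
    the principal axes; with ``n_electrodes=5`` a central electrode is
    added.  All electrodes are vertical.
    """
    tissue = tissue or TissueModel()
    if n_electrodes not in (4, 5):
        raise ValueError("n_electrodes must be 4 or 5")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    a, b, _ = tissue.tumor_semiaxes
    inset = margin + radius * MM / CM
    ra, rb = a - inset, b - inset
    if ra <= 0 or rb <= 0:
        raise ValueError("margin too large: electrodes would not fit inside the tumor")
    cx, cy, cz = tissue.tumor_center
    top = cz + active_length / 2 + z_offset
    ring = {1: (ra, 0.0), 2: (0.0, rb), 3: (-ra, 0.0), 4: (0.0, -rb)}
    electrodes = [
        NeedleElectrode(
            id=eid,
            entry_point=(cx + px, cy + py, top),
            active_length=active_length,
            radius=radius,
        )
        for eid, (px, py) in ring.items()
    ]
    if n_electrodes == 5:
        electrodes.append(
            NeedleElectrode(
                id=CENTRAL_ID,
                entry_point=(cx, cy, top),
                active_length=active_length,
                radius=radius,
            )
        )
    return ElectrodeConfig(tuple(electrodes), label=f"internal{n_electrodes}")


PRESETS = {
    "symmetric": make_symmetric_config,
    "asymmetric": make_asymmetric_config,
    "internal5": lambda tissue=None, **kw: make_internal_config(tissue, n_electrodes=5, **kw),
    "internal4": lambda tissue=None, **kw: make_internal_config(tissue, n_electrodes=4, **kw),
}


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


@dataclass
class LabeledGrid:
    """Cell-centered voxel grid carrying material labels and baseline sigma.

    Coordinates are SI (meters), with the origin at the tumor center.  The
    cell count per axis is odd so that the tumor center and the z = 0 slice
    plane coincide with cell centers.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]          # m
    center: tuple[float, float, float]           # m, tumor center
    label: np.ndarray                            # int16, BACKGROUND/TUMOR/ELECTRODE_BASE+id
    baseline_sigma: np.ndarray                   # float64, S/m
    tissue: TissueModel = field(repr=False, default=None)
    config: ElectrodeConfig = field(repr=False, default=None)

    def axis(self, dim: int) -> np.ndarray:
        """Cell-center coordinates (m) along dimension ``dim``."""
        n = self.shape[dim]
        h = self.spacing[dim]
        return self.center[dim] + (np.arange(n) - (n - 1) / 2) * h

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, m^3."""
        return float(np.prod(self.spacing))

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.label == TUMOR

    @property
    def electrode_ids(self) -> tuple[int, ...]:
        vals = np.unique(self.label[self.label >= ELECTRODE_BASE])
        return tuple(int(v - ELECTRODE_BASE) for v in vals)

    def electrode_mask(self, electrode_id: int) -> np.ndarray:
        return self.label == ELECTRODE_BASE + electrode_id

    def tumor_volume_cm3(self) -> float:
        """Summed volume of tumor-labeled voxels, cm^3."""
        return float(self.tumor_mask.sum() * self.voxel_volume / CM**3)

    def nearest_index(self, point_cm: Sequence[float]) -> tuple[int, int, int]:
        p = np.asarray(point_cm, float) * CM
        return tuple(
            int(np.clip(round((p[d] - self.axis(d)[0]) / self.spacing[d]), 0, self.shape[d] - 1))
            for d in range(3)
        )


def rasterize(
    tissue: TissueModel,
    config: ElectrodeConfig | None,
    spacing: float | Sequence[float] = 0.1,
) -> LabeledGrid:
    """Voxelize the tissue model and electrode configuration.

    ``spacing`` is the voxel edge length in cm (scalar or per-axis).  A voxel
    is labeled as electrode if its center lies within the labeling radius of
    the active segment; the labeling radius is the physical electrode radius
    floored at half the voxel diagonal in the cross-sectional plane, which
    keeps tilted electrodes contiguous on coarse grids.  Remaining voxels are
    tumor if inside the ellipsoid, else background.
    """
    spacing = np.broadcast_to(np.asarray(spacing, float), 3).astype(float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    n = np.maximum(np.round(tissue.box_side / spacing).astype(int), 3)
    n += 1 - n % 2  # odd cell counts center the grid on the tumor
    shape = tuple(int(v) for v in n)
    h = spacing * CM
    center = np.asarray(tissue.tumor_center, float) * CM

    grid = LabeledGrid(
        shape=shape,
        spacing=tuple(h),
        center=tuple(center),
        label=np.zeros(shape, dtype=np.int16),
        baseline_sigma=np.full(shape, tissue.sigma_background0),
        tissue=tissue,
        config=config,
    )
    x, y, z = (grid.axis(d) for d in range(3))
    ax = np.asarray(tissue.tumor_semiaxes, float) * CM
    r2 = (
        ((x[:, None, None] - center[0]) / ax[0]) ** 2
        + ((y[None, :, None] - center[1]) / ax[1]) ** 2
        + ((z[None, None, :] - center[2]) / ax[2]) ** 2
    )
    tumor = r2 <= 1.0
    grid.label[tumor] = TUMOR
    grid.baseline_sigma[tumor] = tissue.sigma_tumor0

    if config is not None:
        # labeling radius floored so every z-slab of a needle owns >= 1 voxel
        floor = 0.5 * np.sqrt(h[0] ** 2 + h[1] ** 2)
        for e in config:
            r_label = max(e.radius * MM, floor)
            _label_segment(grid, e, r_label, x, y, z)
            mask = grid.electrode_mask(e.id)
            if not mask.any():
                raise ValueError(
                    f"electrode {e.id} intersects no voxel centers at spacing {spacing / CM} cm"
                )
            grid.baseline_sigma[mask] = e.sigma
    return grid


def _label_segment(grid, e, r_label, x, y, z):
    p0 = np.asarray(e.entry_point, float) * CM
    p1 = e.tip * CM
    lo = np.minimum(p0, p1) - r_label
    hi = np.maximum(p0, p1) + r_label
    sl = []
    for d, axis_vals in enumerate((x, y, z)):
        i0 = int(np.searchsorted(axis_vals, lo[d]))
        i1 = int(np.searchsorted(axis_vals, hi[d], side="right"))
        if i0 >= i1:
            return
        sl.append(slice(i0, i1))
    X, Y, Z = np.meshgrid(x[sl[0]], y[sl[1]], z[sl[2]], indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    d = p1 - p0
    L2 = d @ d
    t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    sub = grid.label[sl[0], sl[1], sl[2]]
    sub[dist2 <= r_label**2] = ELECTRODE_BASE + e.id
    grid.label[sl[0], sl[1], sl[2]] = sub
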