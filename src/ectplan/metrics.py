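"""Quantitative outputs: treated-volume fractions, slice maps, resistances.

The treated region is where the protocol-maximum field meets or exceeds the
reversible electroporation threshold (400 V/cm by default).  Volumes are
counted in whole voxels; grid-refinement behavior is covered by the
geometry convergence tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CM, LabeledGrid, TUMOR
from .protocol import CoverageField


@dataclass
class CoverageReport:
    """Treated-volume summary at one field threshold."""

    threshold: float            # V/cm
    treated_volume_cm3: float
    tumor_volume_cm3: float
    treated_fraction_pct: float
    slice_fractions_pct: dict[float, float] = field(default_factory=dict)  # z (cm) -> %

    def as_dict(self) -> dict:
        return {
            "threshold_v_per_cm": self.threshold,
            "treated_volume_cm3": self.treated_volume_cm3,
            "tumor_volume_cm3": self.tumor_volume_cm3,
            "treated_fraction_pct": self.treated_fraction_pct,
            "slice_fractions_pct": {str(z): v for z, v in self.slice_fractions_pct.items()},
        }


def treated_fraction(
    coverage: CoverageField,
    grid: LabeledGrid,
    threshold: float = 400.0,
    slice_z_cm: tuple[float, ...] = (0.0, 0.4),
) -> CoverageReport:
    """Fraction of the tumor volume with max field >= ``threshold`` (V/cm).

    Also reports, for each requested z plane, the fraction of the tumor
    cross-section area above threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    tumor = grid.label == TUMOR
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise ValueError("grid contains no tumor voxels")
    hot = coverage.max_field >= threshold
    n_hot = int((hot & tumor).sum())
    vv = grid.voxel_volume / CM**3
    slice_fr = {}
    z_axis = grid.axis(2)
    for z in slice_z_cm:
        k = int(np.argmin(np.abs(z_axis - z * CM)))
        t2d = tumor[:, :, k]
        if t2d.any():
            slice_fr[z] = 100.0 * float((hot[:, :, k] & t2d).sum()) / float(t2d.sum())
    return CoverageReport(
        threshold=threshold,
        treated_volume_cm3=n_hot * vv,
        tumor_volume_cm3=n_tumor * vv,
        treated_fraction_pct=100.0 * n_hot / n_tumor,
        slice_fractions_pct=slice_fr,
    )


@dataclass
class SliceMap:
    """One horizontal slice of the coverage field with the tumor outline."""

    z_cm: float                 # actual plane height used (cm)
    x_cm: np.ndarray            # cell-center coordinates, cm
    y_cm: np.ndarray
    field: np.ndarray           # V/cm, shape (nx, ny)
    tumor_mask: np.ndarray      # bool, shape (nx, ny)
    ellipse_semiaxes_cm: tuple[float, float] | None  # tumor section at this z


def slice_map(coverage: CoverageField, grid: LabeledGrid, z_offset_cm: float = 0.0) -> SliceMap:
    """Extract the coverage field on the horizontal plane nearest ``z_offset_cm``.

    The tumor outline is the analytic ellipsoid cross-section at that
    height: semi-axes (a, b) * sqrt(1 - (z/c)^2), or ``None`` when the plane
    misses the tumor.
    """
    z_axis = grid.axis(2)
    z_m = z_offset_cm * CM + grid.center[2]
    if z_m < z_axis[0] - grid.spacing[2] / 2 or z_m > z_axis[-1] + grid.spacing[2] / 2:
        raise ValueError(f"plane z = {z_offset_cm} cm lies outside the grid")
    k = int(np.argmin(np.abs(z_axis - z_m)))
    ellipse = None
    if grid.tissue is not None:
        a, b, c = grid.tissue.tumor_semiaxes
        rel = (z_axis[k] - grid.center[2]) / CM / c
        if abs(rel) < 1.0:
            s = float(np.sqrt(1.0 - rel**2))
            ellipse = (a * s, b * s)
    return SliceMap(
        z_cm=float((z_axis[k] - grid.center[2]) / CM),
        x_cm=(grid.axis(0) - grid.center[0]) / CM,
        y_cm=(grid.axis(1) - grid.center[1]) / CM,
        field=coverage.max_field[:, :, k].copy(),
        tumor_mask=(grid.label[:, :, k] == TUMOR),
        ellipse_semiaxes_cm=ellipse,
    )


def resistance_from_log(log: pd.DataFrame) -> pd.DataFrame:
    """Per-pair resistance R = V / I from a device log.

    Expects columns ``probe_from``, ``probe_to``, ``amplitude_V``,
    ``measured_current_A``.  Returns the log with ``resistance_ohm`` and a
    dense rank (1 = lowest resistance), and flags the lowest- and
    highest-resistance pairs: these mark the sectors where treatment was
    most and least effective.
    """
    required = {"probe_from", "probe_to", "amplitude_V", "measured_current_A"}
    missing = required - set(log.columns)
    if missing:
        raise ValueError(f"log is missing columns: {sorted(missing)}")
    out = log.copy().reset_index(drop=True)
    if (out["measured_current_A"] <= 0).any():
        bad = out.index[out["measured_current_A"] <= 0].tolist()
        raise ValueError(f"non-positive measured current in rows {bad}")
    out["resistance_ohm"] = out["amplitude_V"] / out["measured_current_A"]
    out["rank"] = out["resistance_ohm"].rank(method="dense").astype(int)
    out["is_lowest"] = out["resistance_ohm"] == out["resistance_ohm"].min()
    out["is_highest"] = out["resistance_ohm"] == out["resistance_ohm"].max()
    return out


def compare_currents(
    computed: dict[tuple[int, int], float],
    measured: dict[tuple[int, int], float],
) -> pd.DataFrame:
    """Measured-vs-computed current table with relative errors.

    Relative error is |computed - measured| / measured.  The returned frame
    carries a ``summary`` attribute dict with the mean and max relative
    error.
    """
    if set(computed) != set(measured):
        raise ValueError(
            f"pair sets differ: computed has {sorted(set(computed) - set(measured))} extra, "
            f"measured has {sorted(set(measured) - set(computed))} extra"
        )
    rows = []
    for (s, k) in computed:
        m = measured[(s, k)]
        c = computed[(s, k)]
        rows.append({
            "probe_from": s,
            "probe_to": k,
            "measured_current_A": m,
            "computed_current_A": c,
            "relative_error": abs(c - m) / m,
        })
    df = pd.DataFrame(rows).sort_values(["probe_from", "probe_to"]).reset_index(drop=True)
    df.attrs["summary"] = {
        "mean_relative_error": float(df["relative_error"].mean()),
        "max_relative_error": float(df["relative_error"].max()),
    }
    return df
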