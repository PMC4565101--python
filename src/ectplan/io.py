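"""Configuration parsing, protocol CSV I/O, and field export.

Run configuration lives in a single YAML (or JSON) file with ``tissue``,
``electrodes``, ``sigma_model``, ``solver``, ``protocol``, ``outputs`` and
``seed`` blocks; unknown keys are rejected by name.  Lengths in config
files are centimeters, except the electrode radius (millimeters).  Field
arrays are exported as legacy ASCII VTK structured points, readable by
ParaView and most scientific viewers.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .geometry import (
    CM,
    ElectrodeConfig,
    LabeledGrid,
    NeedleElectrode,
    PRESETS,
    TissueModel,
    rasterize,
)
from .protocol import PulseEntry, PulseProtocol, clinical_protocol
from .solver import SigmaModel, SolverSettings


class ConfigError(ValueError):
    """A run-configuration file could not be interpreted."""


_TOP_KEYS = {"tissue", "electrodes", "sigma_model", "solver", "grid", "protocol", "outputs", "seed"}


@dataclass
class RunConfig:
    """Fully parsed run configuration."""

    tissue: TissueModel
    electrodes: ElectrodeConfig
    sigma_model: SigmaModel
    settings: SolverSettings
    spacing_cm: float
    protocol: PulseProtocol
    out_dir: Path
    seed: int
    raw: dict = field(repr=False, default_factory=dict)

    @property
    def config_hash(self) -> str:
        """Stable short hash of the raw configuration mapping."""
        canon = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(canon).hexdigest()[:12]

    def build_grid(self) -> LabeledGrid:
        return rasterize(self.tissue, self.electrodes, self.spacing_cm)


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in '{where}' block")


def _build_electrodes(block: dict, tissue: TissueModel) -> ElectrodeConfig:
    _check_keys(block, {"preset", "options", "explicit"}, "electrodes")
    if "explicit" in block:
        electrodes = []
        for i, spec in enumerate(block["explicit"]):
            _check_keys(spec, {"id", "entry_point", "direction", "active_length", "radius", "sigma"},
                        f"electrodes.explicit[{i}]")
            kwargs = dict(spec)
            kwargs["entry_point"] = tuple(kwargs["entry_point"])
            if "direction" in kwargs:
                d = np.asarray(kwargs["direction"], float)
                kwargs["direction"] = tuple(d / np.linalg.norm(d))
            electrodes.append(NeedleElectrode(**kwargs))
        return ElectrodeConfig(tuple(electrodes), label="custom")
    preset = block.get("preset", "symmetric")
    if preset not in PRESETS:
        raise ConfigError(f"unknown electrode preset '{preset}' (choose from {sorted(PRESETS)})")
    return PRESETS[preset](tissue, **block.get("options", {}))


def load_config(source: str | Path | dict) -> RunConfig:
    """Parse a YAML/JSON run-configuration file (or an equivalent mapping)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = yaml.safe_load(text)
    else:
        raw = source
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top-level")

    tissue_block = dict(raw.get("tissue", {}))
    _check_keys(tissue_block, {"box_side", "tumor_center", "tumor_semiaxes", "sigma_tumor0",
                               "sigma_background0", "sigma_boundary"}, "tissue")
    for key in ("tumor_center", "tumor_semiaxes"):
        if key in tissue_block:
            tissue_block[key] = tuple(tissue_block[key])
    try:
        tissue = TissueModel(**tissue_block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid tissue block: {exc}") from exc

    try:
        electrodes = _build_electrodes(dict(raw.get("electrodes", {})), tissue)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid electrodes block: {exc}") from exc

    sm_block = dict(raw.get("sigma_model", {}))
    _check_keys(sm_block, {"E_rev", "E_irr", "f_rev", "f_irr", "enabled"}, "sigma_model")
    try:
        sigma_model = SigmaModel(**sm_block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid sigma_model block: {exc}") from exc

    solver_block = dict(raw.get("solver", {}))
    _check_keys(solver_block, {"band_tol", "max_iter", "relax", "cg_rtol", "cg_maxiter",
                               "robin_face", "robin_L_ref"}, "solver")
    try:
        settings = SolverSettings(**solver_block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid solver block: {exc}") from exc

    grid_block = dict(raw.get("grid", {}))
    _check_keys(grid_block, {"spacing"}, "grid")
    spacing = float(grid_block.get("spacing", 0.1))

    proto_src = raw.get("protocol", "clinical")
    if proto_src == "clinical":
        protocol = clinical_protocol()
    elif isinstance(proto_src, str):
        protocol = read_protocol_csv(proto_src)
    else:
        raise ConfigError("protocol must be 'clinical' or a CSV path")

    out_block = dict(raw.get("outputs", {}))
    _check_keys(out_block, {"directory"}, "outputs")
    out_dir = Path(out_block.get("directory", "ectplan_out"))

    return RunConfig(
        tissue=tissue,
        electrodes=electrodes,
        sigma_model=sigma_model,
        settings=settings,
        spacing_cm=spacing,
        protocol=protocol,
        out_dir=out_dir,
        seed=int(raw.get("seed", 0)),
        raw=raw,
    )


# ---------------------------------------------------------------------------
# protocol CSV
# ---------------------------------------------------------------------------

_PROTOCOL_COLUMNS = {
    "probe_from": ("probe_from", "probe from", "from", "source_id"),
    "probe_to": ("probe_to", "probe to", "to", "sink_id"),
    "distance_cm": ("distance_cm", "distance (cm)", "distance"),
    "amplitude_V": ("amplitude_v", "amplitude (v)", "amplitude", "voltage"),
    "pulse_length_us": ("pulse_length_us", "pulse length (us)", "pulse length (μs)", "pulse_length"),
    "n_pulses": ("n_pulses", "number pulse", "number_pulse", "pulse_count"),
}


def read_protocol_csv(path: str | Path) -> PulseProtocol:
    """Read a pulse protocol from a comma- or tab-delimited table.

    The header must name the device-log columns (probe from/to, distance in
    cm, amplitude in V, pulse length in us, number of pulses); parse errors
    name the offending line.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise ConfigError(f"{path}: no protocol entries")
    try:
        dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t;")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    df = pd.read_csv(_io.StringIO(text), sep=sep)
    if df.empty:
        raise ConfigError(f"{path}: no protocol entries")
    colmap = {}
    lowered = {str(c).strip().lower(): c for c in df.columns}
    for canonical, aliases in _PROTOCOL_COLUMNS.items():
        found = next((lowered[a] for a in aliases if a in lowered), None)
        if found is None and canonical in ("pulse_length_us", "n_pulses"):
            continue  # optional, defaulted
        if found is None:
            raise ConfigError(f"{path}: missing column '{canonical}'")
        colmap[canonical] = found
    entries = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            entries.append(PulseEntry(
                source_id=int(row[colmap["probe_from"]]),
                sink_id=int(row[colmap["probe_to"]]),
                distance_cm=float(row[colmap["distance_cm"]]),
                voltage=float(row[colmap["amplitude_V"]]),
                pulse_length_us=float(row[colmap["pulse_length_us"]]) if "pulse_length_us" in colmap else 100.0,
                pulse_count=int(row[colmap["n_pulses"]]) if "n_pulses" in colmap else 8,
            ))
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"{path}, line {line}: {exc}") from exc
    return PulseProtocol(tuple(entries))


def write_protocol_csv(protocol: PulseProtocol, path: str | Path) -> None:
    rows = [{
        "probe_from": e.source_id,
        "probe_to": e.sink_id,
        "distance_cm": e.distance_cm,
        "amplitude_V": e.voltage,
        "pulse_length_us": e.pulse_length_us,
        "n_pulses": e.pulse_count,
    } for e in protocol]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VTK + JSON export
# ---------------------------------------------------------------------------


def write_vtk(grid: LabeledGrid, fields: dict[str, np.ndarray], path: str | Path) -> None:
    """Write cell-centered scalar fields as a legacy ASCII VTK structured-points file."""
    path = Path(path)
    nx, ny, nz = grid.shape
    hx, hy, hz = (s / CM for s in grid.spacing)
    ox, oy, oz = ((grid.axis(d)[0] - grid.center[d]) / CM for d in range(3))
    with path.open("w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"ectplan {_pkg_version} field export (lengths in cm)\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN {ox:.6g} {oy:.6g} {oz:.6g}\n")
        f.write(f"SPACING {hx:.6g} {hy:.6g} {hz:.6g}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, data in fields.items():
            if data.shape != grid.shape:
                raise ValueError(f"field '{name}' shape {data.shape} != grid shape {grid.shape}")
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            flat = np.asarray(data, float).transpose(2, 1, 0).ravel()
            np.savetxt(f, flat.reshape(-1, 1), fmt="%.6g")


def write_vtk_slice(slice_map, path: str | Path) -> None:
    """Write one coverage slice as a single-layer VTK structured-points file."""
    path = Path(path)
    nx, ny = slice_map.field.shape
    hx = slice_map.x_cm[1] - slice_map.x_cm[0] if nx > 1 else 1.0
    hy = slice_map.y_cm[1] - slice_map.y_cm[0] if ny > 1 else 1.0
    with path.open("w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"ectplan {_pkg_version} slice at z = {slice_map.z_cm:g} cm\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} 1\n")
        f.write(f"ORIGIN {slice_map.x_cm[0]:.6g} {slice_map.y_cm[0]:.6g} {slice_map.z_cm:.6g}\n")
        f.write(f"SPACING {hx:.6g} {hy:.6g} 1\n")
        f.write(f"POINT_DATA {nx * ny}\n")
        f.write("SCALARS max_field_v_per_cm float 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, slice_map.field.T.reshape(-1, 1), fmt="%.6g")
        f.write("SCALARS tumor_mask float 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, slice_map.tumor_mask.T.astype(float).reshape(-1, 1), fmt="%g")


def _round_floats(obj: Any, sig: int = 6) -> Any:
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_summary_json(payload: dict, path: str | Path, config_hash: str | None = None) -> None:
    """Write a run summary with package version and config hash, floats
    rounded to 6 significant digits so repeated runs are byte-identical."""
    body = {"package_version": _pkg_version}
    if config_hash is not None:
        body["config_hash"] = config_hash
    body.update(_round_floats(payload))
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True) + "\n")
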