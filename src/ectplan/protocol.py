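"""The clinical pulse protocol and protocol-level field combination.

Electrochemotherapy delivers trains of 100 us monopolar pulses between
electrode pairs in sequence.  The stationary model solves each pair once
(the pulse train only sets exposure, not the field map) and combines the
per-pair field magnitudes by voxelwise maximum: a voxel counts as
electroporated if any pair drove it above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import LabeledGrid
from .solver import FieldSolution, PairExcitation, SigmaModel, SolverSettings, solve_pair

#: voltage-to-distance dosing heuristic used to program pair amplitudes
DEFAULT_V_TO_D = 1000.0  # V/cm


@dataclass(frozen=True)
class PulseEntry:
    """One row of a device log: an activated pair and its drive parameters."""

    source_id: int
    sink_id: int
    distance_cm: float
    voltage: float
    pulse_length_us: float = 100.0
    pulse_count: int = 8

    def __post_init__(self) -> None:
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")
        if self.pulse_count < 1:
            raise ValueError("pulse_count must be >= 1")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.source_id, self.sink_id)

    @property
    def excitation(self) -> PairExcitation:
        return PairExcitation(self.source_id, self.sink_id, self.voltage)


@dataclass(frozen=True)
class PulseProtocol:
    """Ordered sequence of activated pairs."""

    entries: tuple[PulseEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("protocol must contain at least one entry")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def electrode_ids(self) -> set[int]:
        ids: set[int] = set()
        for e in self.entries:
            ids.update(e.pair)
        return ids

    def validate_against(self, grid: LabeledGrid) -> None:
        present = set(grid.electrode_ids)
        missing = self.electrode_ids - present
        if missing:
            raise ValueError(f"protocol references electrodes absent from the grid: {sorted(missing)}")

    def scaled(self, factor: float) -> "PulseProtocol":
        """Same pairs with all voltages multiplied by ``factor``."""
        return PulseProtocol(tuple(
            PulseEntry(e.source_id, e.sink_id, e.distance_cm, e.voltage * factor,
                       e.pulse_length_us, e.pulse_count)
            for e in self.entries
        ))


# the 8-pair sequence extracted from the pulse-generator log of the treated
# case: 2000 V between adjacent externals (2 cm apart), 1400 V between the
# central electrode and each external (1.4 cm), i.e. 1000 V/cm programmed
_CLINICAL_ROWS = (
    (1, 2, 2.0, 2000.0),
    (1, 4, 2.0, 2000.0),
    (2, 3, 2.0, 2000.0),
    (3, 4, 2.0, 2000.0),
    (5, 1, 1.4, 1400.0),
    (5, 2, 1.4, 1400.0),
    (5, 3, 1.4, 1400.0),
    (5, 4, 1.4, 1400.0),
)

#: per-pair currents measured by the pulse generator during the treatment (A)
_MEASURED_CURRENTS = {
    (1, 2): 14.3,
    (1, 4): 9.1,
    (2, 3): 14.8,
    (3, 4): 9.1,
    (5, 1): 9.7,
    (5, 2): 11.2,
    (5, 3): 10.7,
    (5, 4): 7.0,
}


def clinical_protocol() -> PulseProtocol:
    """The 8-pair pulse sequence recorded for the treated clinical case."""
    return PulseProtocol(tuple(
        PulseEntry(s, k, d, v, 100.0, 8) for (s, k, d, v) in _CLINICAL_ROWS
    ))


def clinical_measured_currents() -> dict[tuple[int, int], float]:
    """Pulse-generator current readings per pair for the clinical case (A)."""
    return dict(_MEASURED_CURRENTS)


def protocol_for_config(
    config,
    voltage_to_distance: float = DEFAULT_V_TO_D,
    pulse_length_us: float = 100.0,
    pulse_count: int = 8,
) -> PulseProtocol:
    """Build a protocol for an electrode layout from the dosing heuristic.

    Ring pairs between consecutive external electrodes (1-2, 2-3, 3-4, 4-1)
    plus, if a central electrode is present, one pair from it to each
    external; each amplitude is ``voltage_to_distance`` times the actual
    axis-to-axis distance at the tumor mid-plane.
    """
    from .geometry import CENTRAL_ID

    ids = sorted(config.ids)
    externals = [i for i in ids if i != CENTRAL_ID]
    entries = []
    ring = list(zip(externals, externals[1:] + externals[:1]))
    for s, k in ring:
        d = config.pair_distance(s, k)
        entries.append(PulseEntry(s, k, round(d, 3), voltage_to_distance * d,
                                  pulse_length_us, pulse_count))
    if CENTRAL_ID in ids:
        for k in externals:
            d = config.pair_distance(CENTRAL_ID, k)
            entries.append(PulseEntry(CENTRAL_ID, k, round(d, 3), voltage_to_distance * d,
                                      pulse_length_us, pulse_count))
    return PulseProtocol(tuple(entries))


@dataclass
class CoverageField:
    """Voxelwise maximum field over a protocol plus per-pair solve summaries."""

    max_field: np.ndarray                 # V/cm
    pair_currents: dict[tuple[int, int], float]
    pair_iterations: dict[tuple[int, int], int]
    pair_converged: dict[tuple[int, int], bool]
    solutions: list[FieldSolution] = field(default_factory=list, repr=False)
    pair_logs: dict[tuple[int, int], list[dict]] = field(default_factory=dict, repr=False)


def combine_max(fields: Iterable[np.ndarray]) -> np.ndarray:
    """Voxelwise maximum of field-magnitude maps (associative, order-free)."""
    fields = list(fields)
    if not fields:
        raise ValueError("no fields to combine")
    shape = fields[0].shape
    for f in fields:
        if f.shape != shape:
            raise ValueError(f"field shape mismatch: {f.shape} vs {shape}")
    out = fields[0].copy()
    for f in fields[1:]:
        np.maximum(out, f, out=out)
    return out


def run_protocol(
    grid: LabeledGrid,
    protocol: PulseProtocol,
    sigma_model: SigmaModel | None = None,
    settings: SolverSettings | None = None,
    keep_solutions: bool = False,
    cumulative: bool = False,
    progress: bool = False,
) -> CoverageField:
    """Solve every protocol entry and combine the fields by voxelwise max.

    Each pair starts from the baseline conductivity (no electroporation
    memory across pairs); with ``cumulative=True`` the conductivity state is
    instead carried forward in protocol order, as a sensitivity mode.
    """
    sigma_model = sigma_model or SigmaModel()
    settings = settings or SolverSettings()
    protocol.validate_against(grid)

    max_field = None
    currents: dict[tuple[int, int], float] = {}
    iters: dict[tuple[int, int], int] = {}
    conv: dict[tuple[int, int], bool] = {}
    logs: dict[tuple[int, int], list[dict]] = {}
    solutions = []
    work_grid = grid
    for entry in protocol:
        try:
            sol = solve_pair(work_grid, entry.excitation, sigma_model, settings)
        except Exception as exc:
            raise RuntimeError(f"solver failed for pair {entry.pair}: {exc}") from exc
        if cumulative:
            from dataclasses import replace as _rep
            work_grid = LabeledGrid(
                shape=grid.shape, spacing=grid.spacing, center=grid.center,
                label=grid.label, baseline_sigma=sol.sigma_final,
                tissue=grid.tissue, config=grid.config,
            )
        max_field = sol.field_magnitude.copy() if max_field is None else \
            combine_max([max_field, sol.field_magnitude])
        currents[entry.pair] = sol.currents[entry.source_id]
        iters[entry.pair] = sol.iterations
        conv[entry.pair] = sol.converged
        logs[entry.pair] = sol.convergence_log
        if keep_solutions:
            solutions.append(sol)
        if progress:
            print(f"  pair {entry.pair}: I = {sol.currents[entry.source_id]:.2f} A "
                  f"({sol.iterations} iterations, converged={sol.converged})")
    return CoverageField(max_field, currents, iters, conv, solutions, logs)
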