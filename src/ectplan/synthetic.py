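"""Synthetic device logs and perturbed electrode placements.

Manual needle insertion places electrodes with millimeter-scale uncertainty.
This module draws seeded placement perturbations (in-plane shifts and small
tilts) and forward-simulates the pulse-generator log — programmed voltage,
logged distance, measured current — so the downstream resistance analysis
can be exercised and validated without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import CENTRAL_ID, CM, MM, ElectrodeConfig, NeedleElectrode, TissueModel, rasterize
from .protocol import PulseProtocol, run_protocol
from .solver import SigmaModel, SolverSettings

LOG_COLUMNS = (
    "probe_from",
    "probe_to",
    "distance_cm",
    "amplitude_V",
    "pulse_length_us",
    "n_pulses",
    "measured_current_A",
)


@dataclass(frozen=True)
class PerturbationSpec:
    """Statistical model of electrode-placement uncertainty.

    ``displacement_sd`` (mm) is the per-axis standard deviation of the 2D
    Gaussian in-plane shift applied to each external electrode;
    ``tilt_sd``/``tilt_max`` (degrees) control the half-normal tilt applied
    to every electrode, with uniform azimuth.
    """

    displacement_sd: float = 2.0   # mm
    tilt_sd: float = 10.0          # degrees
    tilt_max: float = 30.0         # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.displacement_sd < 0 or self.tilt_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.tilt_max < self.tilt_sd:
            raise ValueError("tilt_max must be at least tilt_sd")


@dataclass
class SyntheticLog:
    """A simulated device log plus its provenance."""

    records: pd.DataFrame
    config_label: str
    seed: int
    noise_cv: float

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _tilted(e: NeedleElectrode, tilt_deg: float, azimuth_rad: float) -> NeedleElectrode:
    # needles lean about their entry point, as during manual insertion
    theta = np.deg2rad(tilt_deg)
    direction = np.array([
        np.sin(theta) * np.cos(azimuth_rad),
        np.sin(theta) * np.sin(azimuth_rad),
        -np.cos(theta),
    ])
    return replace(e, direction=tuple(direction))


def perturb_config(
    base: ElectrodeConfig,
    spec: PerturbationSpec,
    max_retries: int = 20,
) -> ElectrodeConfig:
    """Draw one seeded placement perturbation of ``base``.

    External electrodes get an in-plane Gaussian shift (sd per axis =
    ``displacement_sd``); every electrode gets a |N(0, tilt_sd)| tilt capped
    at ``tilt_max`` with uniform azimuth.  Deterministic given the seed.
    Draws that make electrodes overlap are resampled up to ``max_retries``
    times.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.displacement_sd == 0 and spec.tilt_sd == 0:
        return base
    for _ in range(max_retries):
        electrodes = []
        for e in base:
            if e.id != CENTRAL_ID and spec.displacement_sd > 0:
                shift = rng.normal(0.0, spec.displacement_sd * MM / CM, size=2)
                entry = np.asarray(e.entry_point, float)
                entry = entry.copy()
                entry[:2] += shift
                e = replace(e, entry_point=tuple(entry))
            if spec.tilt_sd > 0:
                tilt = min(abs(rng.normal(0.0, spec.tilt_sd)), spec.tilt_max)
                azimuth = rng.uniform(0.0, 2 * np.pi)
                e = _tilted(e, tilt, azimuth)
            electrodes.append(e)
        try:
            return ElectrodeConfig(tuple(electrodes), label=base.label + "+perturbed")
        except ValueError:
            continue
    raise RuntimeError(f"could not draw a non-overlapping perturbation in {max_retries} tries")


def simulate_log(
    config: ElectrodeConfig,
    protocol: PulseProtocol,
    sigma_model: SigmaModel | None = None,
    noise_cv: float = 0.05,
    seed: int = 0,
    tissue: TissueModel | None = None,
    spacing_cm: float = 0.2,
    settings: SolverSettings | None = None,
) -> SyntheticLog:
    """Forward-simulate a pulse-generator log for one electrode layout.

    Solves every protocol pair on a grid rasterized at ``spacing_cm``,
    perturbs each computed current with mean-preserving multiplicative
    lognormal noise of coefficient of variation ``noise_cv``, and logs the
    actual mid-plane axis-to-axis distance rounded to 0.1 cm (the precision
    the device prints).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    tissue = tissue or TissueModel()
    sigma_model = sigma_model or SigmaModel()
    grid = rasterize(tissue, config, spacing_cm)
    coverage = run_protocol(grid, protocol, sigma_model, settings)
    rng = np.random.default_rng(seed)
    rows = []
    for entry in protocol:
        current = coverage.pair_currents[entry.pair]
        if noise_cv > 0:
            s = np.sqrt(np.log1p(noise_cv**2))
            current *= float(np.exp(rng.normal(-0.5 * s**2, s)))
        rows.append({
            "probe_from": entry.source_id,
            "probe_to": entry.sink_id,
            "distance_cm": round(config.pair_distance(entry.source_id, entry.sink_id), 1),
            "amplitude_V": entry.voltage,
            "pulse_length_us": entry.pulse_length_us,
            "n_pulses": entry.pulse_count,
            "measured_current_A": current,
        })
    records = pd.DataFrame(rows, columns=list(LOG_COLUMNS))
    return SyntheticLog(records=records, config_label=config.label, seed=seed, noise_cv=noise_cv)
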