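"""Seeded generators for every input the pipeline needs.

Real counterparts of these inputs (multi-decade 3-hourly reanalysis series
of significant wave height and peak period; sonar-surveyed seagrass pattern
wavelengths versus depth) are not redistributable, so the package generates
statistically plausible stand-ins: a log-normal peak-period climate with a
power-law Hs|Tp relation, pattern observations placed at half the shoaled
wavelength with configurable noise (encoding the Bragg half-wavelength
relation by construction), and seeded white-noise initial fields for the
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .braggsim import SimulationGrid
from .linear_wave_core import shoal_wavelength
from .wave_climate import PatternObservation, WaveClimateSeries

__all__ = [
    "ClimateGenSpec",
    "ObsGenSpec",
    "generate_wave_climate",
    "generate_pattern_observations",
    "generate_initial_noise",
]


@dataclass(frozen=True)
class ClimateGenSpec:
    """Wave-climate generator parameters.

    Peak periods are log-normal (median ``tp_median_s``, log-sd
    ``tp_log_sd``); significant height follows Hs = c * Tp^p * exp(eps)
    with eps ~ N(0, hs_log_sd), so the most bed-stress-energetic events are
    the long-period, high swells. Defaults put the Tp 99-percentile near
    10.4 s, the western-Mediterranean reanalysis regime.
    """

    n_records: int = 10_000
    cadence_h: float = 3.0
    tp_median_s: float = 6.5
    tp_log_sd: float = 0.2
    hs_coeff: float = 0.04
    hs_power: float = 2.0
    hs_log_sd: float = 0.4
    site_depth_m: float = 29.7
    site_label: str = "synthetic-bay"
    start: str = "1980-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.tp_median_s <= 0 or self.tp_log_sd < 0:
            raise ValueError("invalid Tp distribution parameters")
        if self.hs_coeff <= 0 or self.hs_log_sd < 0:
            raise ValueError("invalid Hs conditional-law parameters")


@dataclass(frozen=True)
class ObsGenSpec:
    """Seagrass pattern-observation generator parameters.

    Observations are placed at lam_n = shoal(lam_inf, H)/2 * (1 + eps),
    eps ~ N(0, rel_noise_sd), over depths uniform in [depth_min, depth_max].
    """

    n_obs: int = 50
    depth_min_m: float = 2.0
    depth_max_m: float = 25.0
    lam_inf_m: float = 168.0
    rel_noise_sd: float = 0.1
    site_label: str = "synthetic-site"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.depth_min_m < self.depth_max_m:
            raise ValueError("need 0 < depth_min < depth_max")
        if self.lam_inf_m <= 0 or self.rel_noise_sd < 0:
            raise ValueError("invalid lam_inf or noise sd")


def generate_wave_climate(spec: ClimateGenSpec) -> WaveClimateSeries:
    """Draw a seeded (time, Hs, Tp) series suitable for wave_climate."""
    rng = np.random.default_rng(spec.seed)
    tp = spec.tp_median_s * np.exp(rng.normal(0.0, spec.tp_log_sd, spec.n_records))
    hs = spec.hs_coeff * tp ** spec.hs_power * np.exp(
        rng.normal(0.0, spec.hs_log_sd, spec.n_records))
    times = pd.date_range(spec.start, periods=spec.n_records,
                          freq=pd.Timedelta(hours=spec.cadence_h))
    df = pd.DataFrame({"time": times, "hs_m": hs, "tp_s": tp})
    return WaveClimateSeries(records=df, site_depth=spec.site_depth_m,
                             site_label=spec.site_label)


def generate_pattern_observations(spec: ObsGenSpec) -> list[PatternObservation]:
    """Observations at half the shoaled wavelength, with relative noise."""
    rng = np.random.default_rng(spec.seed)
    depths = rng.uniform(spec.depth_min_m, spec.depth_max_m, spec.n_obs)
    eps = rng.normal(0.0, spec.rel_noise_sd, spec.n_obs)
    obs = []
    for H, e in zip(depths, eps):
        lam_n = 0.5 * shoal_wavelength(spec.lam_inf_m, H) * (1.0 + e)
        obs.append(PatternObservation(depth=float(H), pattern_wavelength=float(lam_n),
                                      site=spec.site_label))
    return obs


def generate_initial_noise(grid: SimulationGrid, amplitude: float,
                           seed: int) -> np.ndarray:
    """Zero-mean Gaussian noise of rms ``amplitude`` on the grid interior,
    exactly zero in the sponge zones."""
    if amplitude <= 0:
        raise ValueError(f"noise amplitude must be > 0, got {amplitude}")
    rng = np.random.default_rng(seed)
    n1 = np.zeros(grid.Nx)
    mask = grid.interior_mask
    draw = rng.normal(0.0, amplitude, int(mask.sum()))
    draw -= draw.mean()
    n1[mask] = draw
    return n1
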