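"""Configuration files, delimited-text readers/writers and run manifests.

The configuration format is a flat ``key: value`` YAML mapping covering the
physical wave parameters, the seagrass parameters and the numerical
simulation settings; unknown keys are rejected and every invariant
violation is reported with the expected range.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .braggsim import SimConfig
from .equilibria import SeagrassParams
from .linear_wave_core import WaveParameters
from .wave_climate import PatternObservation, WaveClimateSeries

__all__ = [
    "CONFIG_SCHEMA",
    "load_config",
    "dump_config",
    "read_climate_csv",
    "write_climate_csv",
    "read_observations_csv",
    "write_table",
    "write_manifest",
]

# key -> (python type, predicate, human-readable constraint)
CONFIG_SCHEMA: dict[str, tuple] = {
    # wave forcing
    "a": (float, lambda v: v >= 0, "wave amplitude [m] >= 0"),
    "T": (float, lambda v: v > 0, "wave period [s] > 0"),
    "g": (float, lambda v: v > 0, "gravitational acceleration [m/s^2] > 0"),
    "rho": (float, lambda v: v > 0, "water density [kg/m^3] > 0"),
    "f_w": (float, lambda v: v > 0, "wave friction factor > 0"),
    # seagrass
    "omega_b": (float, lambda v: v < 0, "background net mortality rate < 0"),
    "omega_c": (float, lambda v: v >= 0, "stress-mortality coupling >= 0"),
    "alpha": (float, lambda v: True, "facilitation coefficient (any sign)"),
    "beta": (float, lambda v: v > 0, "competition coefficient > 0"),
    "delta": (float, lambda v: v >= 0, "dispersion coefficient [m^2/unit] >= 0"),
    "s": (float, lambda v: v >= 0, "topography coefficient [m/density] >= 0"),
    "h": (float, lambda v: v > 0, "bare-bed depth [m] > 0"),
    # numerics
    "interior_wavelengths": (float, lambda v: v > 0, "interior length [lambda] > 0"),
    "sponge_wavelengths": (float, lambda v: v >= 0, "sponge width [lambda] >= 0"),
    "nodes_per_wavelength": (int, lambda v: v >= 32, "nodes per wavelength >= 32"),
    "gamma_max": (float, lambda v: v is None or v >= 0, "sponge damping [1/s] >= 0"),
    "sponge_exponent": (float, lambda v: v >= 2, "sponge ramp exponent >= 2"),
    "steps_per_period": (int, lambda v: v >= 64, "steps per period >= 64 (dt <= T/64)"),
    "M": (float, lambda v: v >= 1, "morphological acceleration factor >= 1"),
    "bio_timescale": (float, lambda v: v > 0, "seconds per biological unit > 0"),
    "n_periods": (float, lambda v: v > 0, "simulated forcing periods > 0"),
    "spinup_periods": (float, lambda v: v >= 1, "spin-up periods >= 1"),
    "seed": (int, lambda v: v >= 0, "random seed >= 0"),
    "topography_frozen": (bool, lambda v: True, "boolean"),
    "init_noise_rel": (float, lambda v: v > 0, "initial noise rms / n0 > 0"),
    "branch": (str, lambda v: v in ("vegetated", "bare"), "vegetated|bare"),
    "snapshot_every_periods": (float, lambda v: v >= 1, "snapshot stride >= 1"),
    "stop_at_equilibrium": (bool, lambda v: True, "boolean"),
    "equilibrium_rel_drift": (float, lambda v: v > 0, "relative drift > 0"),
    "equilibrium_periods": (int, lambda v: v >= 1, "consecutive quiet periods >= 1"),
}

_WAVE_KEYS = ("a", "T", "g", "rho", "f_w")
_SEAGRASS_KEYS = ("omega_b", "omega_c", "alpha", "beta", "delta", "s", "h")


def _defaults() -> dict:
    cfg = SimConfig()
    flat = {k: getattr(cfg.wp, k) for k in _WAVE_KEYS}
    flat.update({k: getattr(cfg.sp, k) for k in _SEAGRASS_KEYS})
    for key in CONFIG_SCHEMA:
        if key not in flat:
            flat[key] = getattr(cfg, key)
    return flat


def load_config(path: str | Path) -> SimConfig:
    """Read and validate a flat YAML configuration, filling defaults.

    Unknown keys are rejected; every invariant violation is collected and
    reported together with the expected type/range.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key: value mapping")
    unknown = sorted(set(raw) - set(CONFIG_SCHEMA))
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}; "
                         f"known keys: {sorted(CONFIG_SCHEMA)}")
    flat = _defaults()
    errors = []
    for key, value in raw.items():
        typ, pred, desc = CONFIG_SCHEMA[key]
        if typ is float and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        if value is not None and not isinstance(value, typ):
            errors.append(f"{key}: expected {typ.__name__}, got {value!r} ({desc})")
            continue
        if not pred(value):
            errors.append(f"{key}: value {value!r} violates: {desc}")
            continue
        flat[key] = value
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    wp = WaveParameters(**{k: flat[k] for k in _WAVE_KEYS})
    sp = SeagrassParams(**{k: flat[k] for k in _SEAGRASS_KEYS})
    sim_keys = [k for k in CONFIG_SCHEMA if k not in _WAVE_KEYS + _SEAGRASS_KEYS]
    return SimConfig(wp=wp, sp=sp, **{k: flat[k] for k in sim_keys})


def dump_config(config: SimConfig) -> dict:
    """Flatten a SimConfig back to the normalized key: value mapping."""
    flat = {k: getattr(config.wp, k) for k in _WAVE_KEYS}
    flat.update({k: getattr(config.sp, k) for k in _SEAGRASS_KEYS})
    for key in CONFIG_SCHEMA:
        if key not in flat:
            flat[key] = getattr(config, key)
    return flat


def read_climate_csv(path: str | Path, site_depth: float,
                     site_label: str = "") -> WaveClimateSeries:
    """Parse a ``time,hs_m,tp_s`` CSV into a validated climate series.

    Columns are header-keyed, so order is free; rows with missing or
    invalid values are reported by index.
    """
    df = pd.read_csv(path)
    missing = {"time", "hs_m", "tp_s"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    try:
        df["time"] = pd.to_datetime(df["time"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamp(s): {exc}") from exc
    for col in ("hs_m", "tp_s"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[df[["hs_m", "tp_s"]].isna().any(axis=1)
                   | (df["hs_m"] < 0) | (df["tp_s"] <= 0)].tolist()
    if bad:
        raise ValueError(f"{path}: invalid Hs/Tp at row(s) {bad[:20]}")
    df = df[["time", "hs_m", "tp_s"]]
    return WaveClimateSeries(records=df, site_depth=site_depth,
                             site_label=site_label or str(path))


def write_climate_csv(series: WaveClimateSeries, path: str | Path) -> None:
    df = series.records.copy()
    df["time"] = pd.to_datetime(df["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    cols = ["time", "hs_m", "tp_s"] + [c for c in df.columns
                                       if c not in ("time", "hs_m", "tp_s")]
    df[cols].to_csv(path, index=False, lineterminator="\r\n")


def read_observations_csv(path: str | Path) -> list[PatternObservation]:
    """Parse a ``depth_m,pattern_wavelength_m,site`` CSV."""
    df = pd.read_csv(path)
    missing = {"depth_m", "pattern_wavelength_m"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if "site" not in df.columns:
        df["site"] = ""
    return [
        PatternObservation(depth=float(r.depth_m),
                           pattern_wavelength=float(r.pattern_wavelength_m),
                           site=str(r.site))
        for r in df.itertuples()
    ]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """RFC-4180-style comma-separated output with header, fixed column order."""
    df.to_csv(path, index=False, lineterminator="\r\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(path: str | Path, command: str, params: dict,
                   seed: int | None = None,
                   inputs: list[str | Path] = ()) -> Path:
    """Write a JSON run manifest (parameters, seed, version, input digests)."""
    def _jsonable(v):
        if isinstance(v, (WaveParameters, SeagrassParams)):
            return asdict(v)
        if hasattr(v, "tolist"):
            return v.tolist()
        return v

    manifest = {
        "tool": "braggrass",
        "version": __version__,
        "command": command,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "inputs": {str(p): _digest(Path(p)) for p in inputs if Path(p).exists()},
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
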