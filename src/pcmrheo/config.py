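"""Run configuration: a single YAML file with strict key checking.

Every stage reads its parameters from one nested mapping; unknown keys
are rejected so typos fail loudly, and each run writes the fully
resolved configuration next to its outputs for reproducibility.
"""
from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

#: Full schema with defaults.  ``None`` marks optional values.
DEFAULTS: dict = {
    "seed": 0,
    "simulate": {
        "medium": "maxwell",          # newtonian | maxwell
        "eta": None,                  # Pa·s, newtonian
        "eta0": 31.8,                 # Pa·s, maxwell
        "tau": 4.6,                   # s, maxwell
        "temperature_K": 303.15,
        "bead_radius_m": 50e-9,
        "n_beads": 300,
        "n_frames": 10000,
        "dt": 0.015,
        "droplet_radius_um": None,
    },
    "track": {
        "diameter": 7,
        "min_mass": 0.0,
        "percentile_threshold": 64.0,
        "noise_scale": 1.0,
        "max_disp": 5.0,
        "memory": 3,
        "min_length": 100,
        "subtract_static_offset": False,
    },
    "rheo": {
        "lag_min": 0.015,
        "lag_max": 100.0,
        "points_per_decade": 20,
        "span_fraction": 0.05,
        "bead_radius_m": 50e-9,
        "temperature_K": 303.15,
        "dimensionality": 2,
    },
    "frap": {
        "mode": "in_vitro_reference",
        "bleach_index": None,
        "n_boot": 500,
    },
    "quant": {
        "threshold_method": "otsu",
        "fixed_threshold": None,
        "watershed": False,
        "min_size": 9,
        "pixel_size_um": 0.1,
    },
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict) and not isinstance(value, dict):
            raise ConfigError(f"{where} must be a mapping")
        if isinstance(defaults[key], dict):
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Resolve defaults ← YAML file ← explicit overrides (highest wins)."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigError("configuration file must contain a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def write_resolved(cfg: dict, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.json"
    path.write_text(json.dumps(cfg, indent=2))
    return path
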