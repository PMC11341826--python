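"""Shared plain-text (YAML key: value) configuration for the CLI.

Keys mirror the keyword arguments of the library functions; unknown
keys raise so typos do not silently fall back to defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

DEFAULTS: dict = {
    # spectral_features
    "cloud_threshold": 50.0,  # percent cloud probability
    # unmixing thresholds
    "ndvi_veg_min": 0.8,
    "ndvi_bare_max": 0.2,
    "ndwi_water_min": 0.3,
    "endmember_strategy": "percentile-purity",
    # phenology / grid
    "rmmeh_passes": 2,
    "year_length": 365,
    # cube
    "eps_floor": 0.05,
    "year": 2020,
    # cooling
    "window": 5,
    "min_valid": 10,
    "min_green_sd": 0.05,
    # validation
    "block_size_m": 200.0,
    "min_valid_frac": 0.5,
    # synthetic scene
    "seed": 0,
    "shape": [128, 128],
    "patch_scale": 16,
    "noise_sd": 0.01,
    "cloud_prob": 0.3,
}


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file of flat keys."""
    cfg = dict(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(DEFAULTS)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    return cfg
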