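"""Flat key-value configuration with defaults <- file <- flags precedence."""

from __future__ import annotations

import json
from pathlib import Path

__all__ = ["DEFAULTS", "load_config", "merge_config"]

DEFAULTS: dict[str, object] = {
    "population.size": 10,
    "population.peak_rate": 10.0,
    "model.sd_tuning": 0.6,
    "model.sd_window_ms": 300.0,
    "model.n_reps": 100,
    "fit.bounds_sd_tuning": [0.05, 3.0],
    "fit.bounds_sd_window_ms": [1.0, 2000.0],
    "fit.n_calls": 50,
    "fit.n_runs": 20,
    "fit.objective_target": "human_reported",
    "seed": 0,
}


def load_config(path: str | Path | None) -> dict[str, object]:
    """Read a flat JSON config file; unknown keys are rejected."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a JSON object")
    unknown = set(cfg) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def merge_config(file_cfg: dict | None = None, **flag_overrides) -> dict[str, object]:
    """Defaults overridden by the config file, overridden by explicit flags.

    Flag overrides use the flat key names with '.' replaced by '_';
    ``None`` values are ignored (flag not given).
    """
    merged = dict(DEFAULTS)
    merged.update(file_cfg or {})
    for key, value in flag_overrides.items():
        if value is None:
            continue
        dotted = key.replace("__", ".")
        if dotted not in DEFAULTS:
            raise KeyError(f"unknown config key {dotted!r}")
        merged[dotted] = value
    return merged
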