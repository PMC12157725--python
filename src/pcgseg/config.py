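"""Pipeline configuration: flat defaults plus optional YAML overrides."""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

DEFAULTS: dict[str, Any] = {
    "pcg": {"band": [40.0, 450.0], "cheby_order": 3, "ripple_db": 1.0},
    "ecg": {"band": [0.5, 100.0], "butter_order": 2, "mains_hz": 50.0},
    "hsmm": {
        "frame_rate": 50.0,
        "s1_win_ms": 122.0,
        "s2_win_ms": 92.0,
        "kurtosis_win_ms": 200.0,
        "kurtosis_hop_ms": 1.0,
        "emission": "logistic",  # or "gaussian"
    },
    "s1": {
        "threshold_frac": 0.7,
        "shannon_scale": 0.4,
        "ase_window_ms": 20.0,
        "ase_hop_ms": 10.0,
    },
    "s2": {
        "ci_level": 0.95,
        "window_ms": 20.0,
        "overlap": 0.5,
        "lobe_prominence": 0.1,
        "reference": "model",  # or "recording"
    },
    "eval": {"window_ms": 100.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Return the default configuration, merged with a YAML file if given."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, override)
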