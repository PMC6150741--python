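"""Run configuration: defaults, YAML/JSON loading, and config echo."""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULT_CONFIG: dict = {
    "filter": {"mode": "gaussian", "scale_mm": 2.0},
    "quantization": {"bins": 32},
    "texture": {
        "distance": 1,
        # "3d" uses the 26-neighborhood / 26-connectivity / 13 run directions
        # for the high-order families; "2d" restricts them in-plane.
        "high_order_geometry": "3d",
    },
    "features": {"classes": "all"},
    "simulate": {
        "subjects": 14,
        "noise_cv": 0.10,
        "mask_jitter": 0,
        "readers": 1,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in out:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(value, dict) and isinstance(out[key], dict):
            for sub, sub_val in value.items():
                if sub not in out[key]:
                    raise ConfigError(f"unknown config key {key}.{sub}")
                out[key][sub] = sub_val
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Resolve the run config: defaults <- file (YAML or JSON) <- overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data:
            cfg = _merge(cfg, data)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def echo_config(cfg: dict, out_dir: str | Path) -> Path:
    """Write the fully resolved config next to a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "config_resolved.yaml"
    path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
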