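"""Run configuration: YAML loading over the pipeline's published defaults."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

# All defaults with a clinical/printed origin: canonical 512-px resize, 48-px
# patches, stride-5 sliding, 10,000 patches/image, batch 128, dropout 0.2,
# SGD lr 1e-3 with factor 0.3 / patience 10 / early stop 40, binarization
# threshold 0.5, 1.8x OD ellipse, 80-px macula square.
DEFAULTS: dict = {
    "preprocess": {
        "side": 512,
        "clip_limit": 2.0,
        "tile_grid": 8,
        "apply_clahe": True,
    },
    "patch": {
        "window": 48,
        "stride": 5,
        "n_per_image": 10000,
        "seed": 0,
    },
    "network": {
        "block_channels": [32, 64, 128],
        "dropout_p": 0.2,
        "upsample": "nearest",
    },
    "train": {
        "batch_size": 128,
        "val_fraction": 0.10,
        "lr_init": 1.0e-3,
        "lr_factor": 0.3,
        "lr_patience": 10,
        "early_stop_patience": 40,
        "momentum": 0.0,
        "max_epochs": 150,
        "seed": 0,
    },
    "postprocess": {
        "od": {"enabled": True, "scale": 1.8},
        "macula": {"enabled": True, "side": 80},
    },
    "prp": {
        "threshold": 0.5,
        "min_area": 10,
        "min_marks": 30,
        "min_quadrants": 3,
        "od_margin_microns": 500.0,
        "macula_margin_microns": 3000.0,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, deep-merged with a YAML file when given."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config {path} must be a mapping")
    return _deep_merge(DEFAULTS, user)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]
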