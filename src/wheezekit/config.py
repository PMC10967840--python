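"""Centralized run configuration: YAML loading, validation, manifests.

Every stage default — the 60-2000 Hz order-10 bandpass, SG window 9, db3
level 4, 1024-sample Hann window at 50% overlap, 64 mel bands over
60-1200 Hz, the 50 Hz / 100 ms detector rules, the 20% test split, five
folds and Adam lr 0.001 — lives in :data:`DEFAULTS` and nowhere else.
Unknown keys anywhere in a user config are rejected before any stage runs.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "channel": "contact",
    "simulate": {
        "n_recordings": 8,
        "duration_s": 30.0,
        "sample_rate": 20000.0,
        "respiration_rate": 15.0,
        "class_mix": [0.5, 0.5, 0.0],
        "ambient_level": 1.0,
    },
    "preprocess": {
        "low_hz": 60.0,
        "high_hz": 2000.0,
        "bp_order": 10,
        "sg_window": 9,
        "sg_polyorder": 3,
        "dwt_level": 4,
        "dwt_threshold": "universal",
        "segment_s": 5.0,
    },
    "melspec": {
        "n_bands": 64,
        "fmin": 60.0,
        "fmax": 1200.0,
        "overlap": 0.5,
        "norm": "peak",
        "db_floor": -80.0,
    },
    "detector": {
        "baseline_margin_db": 8.0,
        "link_tolerance_hz": 50.0,
        "min_duration_s": 0.100,
        "min_freq_hz": 100.0,
        "enforce_min_freq": True,
        "max_gap_frames": 0,
    },
    "respiration": {
        "cutoff_hz": 5.0,
        "order": 10,
        "smooth_window_s": 0.5,
        "prominence_fraction": 0.1,
    },
    "classifier": {
        "dense_width": 128,
        "learning_rate": 0.001,
        "batch_size": 32,
        "max_epochs": 100,
        "patience": 10,
        "test_fraction": 0.2,
        "k_folds": 5,
        "grouped_split": True,
    },
}


class ConfigError(ValueError):
    """Raised for unknown keys or malformed config files."""


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    merged = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{here} must be a mapping")
            merged[key] = _merge(defaults[key], value, here)
        else:
            merged[key] = value
    return merged


def load_config(path: str | Path | None = None, overrides: dict | None = None
                ) -> dict:
    """Defaults, overlaid with a YAML file and/or an overrides dict."""
    config = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
        config = _merge(config, user)
    if overrides:
        config = _merge(config, overrides)
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(run_dir: str | Path, config: dict, outputs: list[Path]
                   ) -> Path:
    """Record the config hash, seed and a content hash of every artifact."""
    run_dir = Path(run_dir)
    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": config.get("seed"),
        "outputs": {str(p.relative_to(run_dir)): file_sha256(p)
                    for p in sorted(outputs)},
    }
    path = run_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
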