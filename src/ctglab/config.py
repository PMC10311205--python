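"""Structured run configuration: defaults, YAML files, flag overrides.

Keys are dotted (``preprocess.max_gap_s``); unknown keys are rejected so
typos fail loudly, and the effective (defaults-merged) configuration is
echoed to the log by every CLI command.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "io": {
        "physiological_guard": True,
    },
    "preprocess": {
        "max_gap_s": 600.0,
        "segment_len_s": 1800.0,
        "max_start_before_delivery_s": 5400.0,
        "interpolation": "linear",
    },
    "baseline": {
        "mode": "variable",
        "T0_s": 1200.0,
        "bands_bpm": [[0.0, 0.1], [0.1, 1.0], [1.0, 3.0], [3.0, 7.0]],
        "grid_stride": 4,
        "T_clamp_s": [300.0, 3600.0],
        "stability_C": 1.0,
    },
    "events": {
        "min_duration_s": 15.0,
        "contraction_threshold_mmhg": 10.0,
        "contraction_min_duration_s": 30.0,
    },
    "model": {
        "features": ["b_min", "b_max", "acc_area", "dec_area"],
        "outcome_threshold_ph": 7.05,
        "l2_C": 1e4,
        "k_folds": 5,
    },
    "simulate": {},  # populated from SimParams field names at import time
    "seed": 0,
    "verbosity": "info",
}


def _sim_defaults() -> dict[str, Any]:
    from dataclasses import fields
    from .synthetic import SimParams

    out = {}
    for f in fields(SimParams):
        v = getattr(SimParams(), f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        here = f"{path}.{k}" if path else k
        if k not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[k], dict) and isinstance(v, dict):
            out[k] = _deep_merge(base[k], v, here)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file and then with
    programmatic overrides (dotted keys allowed in ``overrides``)."""
    base = copy.deepcopy(DEFAULTS)
    base["simulate"] = _sim_defaults()
    cfg = base
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        cfg = _deep_merge(cfg, doc)
    if overrides:
        nested: dict = {}
        for key, val in overrides.items():
            node = nested
            parts = key.split(".")
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = val
        cfg = _deep_merge(cfg, nested)
    return cfg


def log_effective_config(cfg: dict) -> None:
    logger.info("effective configuration:\n%s", yaml.safe_dump(cfg, sort_keys=True))
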