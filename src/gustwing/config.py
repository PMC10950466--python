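"""YAML configuration with ``segmentation``, ``wingbeat``, ``simulation``
and ``models`` sections; unknown keys are rejected early."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .synthetic_flight import SimConfig

DEFAULTS = {
    "segmentation": {"window_s": 15.0, "min_tail_s": 10.0},
    "wingbeat": {"smooth_events": 20, "diff_events": 20, "min_prominence_g": 0.5},
    "simulation": {},  # SimConfig field overrides
    "models": {"k": 10, "ar1": False},
}


def load_config(path=None) -> dict:
    cfg = {sec: dict(vals) for sec, vals in DEFAULTS.items()}
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    sim_fields = {f.name for f in fields(SimConfig)}
    for sec, vals in user.items():
        if sec not in cfg:
            raise KeyError(f"unknown config section {sec!r}")
        for key, val in (vals or {}).items():
            if sec == "simulation":
                if key not in sim_fields:
                    raise KeyError(f"unknown simulation key {key!r}")
            elif key not in cfg[sec]:
                raise KeyError(f"unknown {sec} key {key!r}")
            cfg[sec][key] = val
    return cfg


def sim_config_from(cfg: dict, seed: int | None = None) -> SimConfig:
    kwargs = dict(cfg.get("simulation", {}))
    if seed is not None:
        kwargs["seed"] = seed
    return SimConfig(**kwargs)
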