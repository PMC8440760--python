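"""Pipeline configuration: flat nested-dict defaults, optionally overridden
from a YAML file.  All lengths are in pixels at the working resolution;
detection defaults are stated at phantom scale (512x416) and scale linearly
with image width relative to full-field resolution (4096x3328)."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "preprocess": {
        "gamma": 2.0,
        "fg_threshold": 0.05,
        "border_margin_px": 4,
    },
    "registration": {
        "sigma_fluid": 1.0,
        "sigma_diffusion": 4.0,
        "pyramid_factors": [4, 2, 1],
        "iterations": 80,
        "step_cap": 2.0,
    },
    "subtraction": {
        "residual_frac_threshold": 0.5,
        "window_half_px": 5,
    },
    "detection": {
        "window": 3,
        "threshold": 0.2,
        "min_area": 4,
        "gap_close_radius": 1,
        "tol_px": 8.0,
    },
    "features": {
        "glcm_levels": 32,
    },
    "classify": {
        "scheme": "LOPO",
        "k": 5,
        "p_cut": 0.05,
        "top_k": 20,
    },
}


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, deep-merged with an optional YAML override file."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        _merge(cfg, override)
    return cfg


def _merge(base: dict, override: dict) -> None:
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v
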