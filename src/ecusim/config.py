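"""Run configuration: defaults, YAML loading and strict merging.

The default configuration carries the full published parameterization
(population PK-PD estimates, dosing tables are in :mod:`ecusim.regimens`),
so a simulation run with no overrides reproduces the headline dosing
experiments.  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

__all__ = ["default_config", "load_config", "merge_config", "config_hash"]


def default_config() -> dict:
    return {
        "population": {
            # PK (typical 70-kg subject)
            "cl_typ": 0.163, "v_typ": 6.42, "vmax_typ": 29.6, "km": 37.9,
            "iiv_cl_cv": 43.4, "iiv_v_cv": 37.1, "iov_cl_cv": 34.4,
            "add_err": 4.33, "prop_err_radboud": 0.0247,
            "prop_err_sanquin": 0.248, "ref_weight": 70.0,
            "allometric_cl": 0.75, "allometric_v": 1.0,
            # PD
            "base": 100.7, "imax": 0.96, "ic50": 22.0, "gamma": 5.42,
            "iiv_base_cv": 23.0, "iiv_ic50_cv": 38.5, "prop_err": 0.089,
        },
        "cohort": {
            "n": 2000,
            "age_range": [1.0, 79.0],
            "path": None,          # load a CSV instead of generating
        },
        "trial": {
            "strategy": "standard",
            "study": "loading",
            "horizon": 28.0,
            "dt": 0.1,
            "threshold": 10.0,
            "run_in_intervals": 10,
            "day7_time": 6.0,       # "day 7" evaluation time (t = d - 1)
            "measure_trough_with_error": False,
        },
        "seed": 0,
    }


def merge_config(base: dict, override: dict, path: str = "") -> dict:
    """Recursively merge ``override`` into ``base``; unknown keys raise."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in base:
            raise KeyError(f"unknown configuration key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = merge_config(base[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Default configuration, optionally overridden by a YAML file."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return merge_config(cfg, override)


def config_hash(cfg: dict) -> str:
    """Short stable hash identifying a configuration."""
    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
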