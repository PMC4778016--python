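"""Pipeline configuration: defaults, YAML round trip, hashing.

A configuration is a plain nested dict; :func:`default_config` holds
the canonical analysis settings (STARS cut-offs of 100 steps for
annual/decadal series and 800 years for coarse composites, t-test
significance 0.1, Huber parameter 1, 1000 bootstrap draws) and user
files are deep-merged over it, so a config file only needs the keys it
changes.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .errors import InvalidParameterError

__all__ = ["default_config", "load_config", "merge_config", "config_hash", "save_config"]


def default_config() -> dict:
    return {
        "seeds": {"simulate": 1, "boottest": 2, "fieldcorr": 3, "sea": 4},
        "simulate": {
            "n_years": 500,
            "n_sites": 20,
            "base_p": 0.02,
            "lfy_p": 0.4,
            "temperature": {
                # piecewise mean (start, length, level); middle segment cold
                "segments": [[0, 150, 0.5], [150, 150, -0.5], [300, 200, 0.5]],
                "ar1": 0.3,
                "sd": 0.25,
            },
            "grid": {"nlat": 24, "nlon": 36, "n_years": 80,
                     "coupling": 0.5, "noise_sd": 0.866,
                     "block": [[8, 14], [10, 20]]},
        },
        "stars": {
            "annual": {"cutoff_l": 100, "alpha": 0.1, "huber_h": 1.0,
                       "prewhiten": False, "subsample_frac": 0.5},
            "coarse": {"cutoff_l": 800, "alpha": 0.1, "huber_h": 1.0,
                       "prewhiten": False, "subsample_frac": 0.5},
        },
        "lfy": {"alpha": 0.05, "min_fraction": 0.2},
        "bootstrap": {"n_boot": 1000},
        "field": {"months": [4, 5], "alpha": 0.1, "n_perm": 500,
                  "sea_n_boot": 500, "n_events": 5},
        "processing": {"window": 100, "step": 10, "transform": "sqrt"},
    }


def merge_config(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults deep-merged with an optional YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise InvalidParameterError(f"{path}: config must be a mapping")
        cfg = merge_config(cfg, user)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration, for provenance headers."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
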