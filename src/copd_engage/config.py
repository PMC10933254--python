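"""Study configuration: defaults, YAML loading, per-stage seed derivation."""

from __future__ import annotations

import copy
import zlib
from typing import Mapping, Optional

import numpy as np
import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "stage_seed"]

#: All printed study constants live here: 70-day windows, 21-day transition
#: window, 33%/66% class boundaries, 10-day course limit, 3-day horizon,
#: -55..+70 prediction days, 1000 series per group, 75-25 split, 5 folds.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "data": None,  # {"symptoms": path, "medications": path, "profiles": path}
    "cohort": {
        "n_users": 400,
    },
    "engagement": {
        "min_reports": 5,
        "signal_rise": 0.5,
        "gap_days": 14,
    },
    "simulation": {
        "n_per_group": 1000,
        "bin_halfwidth": 3,
        "min_source_series": 3,
    },
    "features": {
        "horizon": 3,
        "start": -55,
        "end": 70,
        "reporting_days_only": False,
    },
    "model": {
        "test_fraction": 0.25,
        "k": 5,
        "budget": 30,
        "bootstrap_reps": 1000,
        "logistic_baseline": True,
    },
}


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: Optional[str] = None,
                overrides: Optional[Mapping] = None) -> dict:
    """Merge the default study config with a YAML file and/or overrides."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        config = _merge(config, loaded)
    if overrides:
        config = _merge(config, overrides)
    return config


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic named substream seed for one pipeline stage."""
    ss = np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0])
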