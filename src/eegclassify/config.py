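"""Run configuration: YAML schema with full defaults and provenance.

A run configuration drives the end-to-end pipeline (dataset source,
preprocessing, artifact removal, feature options, selection chain, ensemble
and validation settings, reporting).  Any key omitted from a user file falls
back to the documented default; CLI flags override their config keys.  Every
report carries a provenance block (config hash, seed, package version) so
reruns with an equal hash are byte-comparable.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config", "config_hash",
           "provenance"]

DEFAULT_CONFIG: dict = {
    "dataset": {
        "source": "synthetic",      # synthetic | edf | text
        "dir": "cohort",            # where files + manifest live / are written
        "manifest": None,           # defaults to <dir>/manifest.csv
        "format": "edf",            # written format for synthetic cohorts
        "n_channels": 16,           # text reader needs these two
        "fs": 128.0,
    },
    "synthetic": {
        "n_control": 14, "n_patient": 14,
        "fs": 128.0, "duration": 60.0, "n_channels": 16,
        "subject_effect_sd": 0.3,
        "noise_exponent": 1.0, "noise_amplitude": 8.0,
        "blink_rate": 0.0, "emg_rate": 0.0,
        "band_amplitudes": {"delta": 15.0, "theta": 10.0,
                            "alpha": 20.0, "beta": 5.0},
        "patient_multipliers": {"delta": 1.0, "theta": 1.3,
                                "alpha": 0.7, "beta": 1.0},
    },
    "preprocess": {
        "band_lo": 0.5, "band_hi": 50.0,
        "epoch_len": 6.0, "overlap": 2.0,
        "zscore": False,
    },
    "artifact": {
        "method": "none",           # none | atar | hook
        "beta": 0.1, "wavelet": "db4", "level": 5, "mode": "elastic",
    },
    "features": {
        "seg_len": None,            # Welch segment length; None = 1 s
        "overlap_frac": 0.5, "window": "hann",
    },
    "selection": {
        "chain": ["variance", "mrmr"],
        "k": 50, "tau": 1.0e-10,
    },
    "ensemble": {
        "members": ["svm_rbf", "knn", "gradient_boosting", "extra_trees"],
        "mode": "vote_soft",
        "weights": None,
        "tuning": {"n_iter": 25, "folds": 5, "seed": 0},
    },
    "validation": {
        "schemes": ["loso"],        # any of random_split | kfold_epoch | loso
        "k": 5, "test_frac": 0.5,
        "seed": 0,
    },
    "report": {
        "out_dir": "reports",
        "bootstrap_B": 2000, "level": 0.95,
        "threshold_step": 0.001,
    },
}


def merge_config(base: dict, override: dict) -> dict:
    """Deep-merge ``override`` into a copy of ``base``."""
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML config (optional) over the defaults, then apply overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        cfg = merge_config(cfg, user)
    if overrides:
        cfg = merge_config(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def provenance(cfg: dict, seed: int | None = None) -> dict:
    from . import __version__
    return {
        "config_hash": config_hash(cfg),
        "seed": seed if seed is not None else cfg["validation"]["seed"],
        "version": __version__,
    }
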