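"""Experiment configuration: YAML loading, defaults, and resolved-config
provenance written next to every run's outputs."""

from __future__ import annotations

import copy
import json
import platform
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

import bpfuse

__all__ = ["DEFAULT_CONFIG", "PROFILES", "load_config", "resolve_config", "write_resolved_config"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "profile": "desk",
    "phantom": {
        "n_cases": 120,
        "prevalence": 0.5,
        "volume_shape": [16, 64, 64],
        "spacing": [3.0, 1.0, 1.0],
        "distractor_rate": 0.3,
        "noise_sigma": 0.04,
        "gland_semiaxes_mm": [14.0, 20.0, 20.0],
        "lesion_radius_mm": [4.0, 7.0],
    },
    "preprocess": {
        "spacing": [3.0, 1.0, 1.0],
        "crop": [8, 32, 32],
        "center": "image",
    },
    "model": {
        "families": ["3ch", "me", "meca"],
        "use_clinical": True,
        "stage_widths": [6, 12],
        "blocks_per_stage": [1, 1],
        "dropout": 0.2,
        "attention_heads": 2,
    },
    "train": {
        "lr": 3e-4,
        "l1_weight": 3e-5,
        "l2_weight": 3e-5,
        "epochs": 8,
        "batch_size": 8,
        "rotation_degrees": 0.0,
        "augment": True,
        "selection_metric": "VAL_AUC",
    },
    "evaluate": {"threshold": 0.5, "n_boot": 500},
    "fairness": {"min_stratum_n": 20, "n_boot": 200},
}

# the full-scale profile restores the published architecture/optimizer values
PROFILES: dict[str, dict[str, Any]] = {
    "desk": {},
    "full": {
        "phantom": {"volume_shape": [32, 224, 224], "spacing": [3.0, 0.5, 0.5]},
        "preprocess": {"spacing": [3.0, 0.5, 0.5], "crop": [32, 224, 224]},
        "model": {
            "stage_widths": [64, 128, 256, 512],
            "blocks_per_stage": [1, 2, 3, 4],
            "dropout": 0.5,
        },
        "train": {"lr": 3e-5, "epochs": 100, "batch_size": 4, "rotation_degrees": 10.0},
    },
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: Optional[str | Path] = None) -> dict:
    """Load a YAML config merged over the profile and package defaults."""
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    profile = user.get("profile", DEFAULT_CONFIG["profile"])
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {sorted(PROFILES)}")
    cfg = _deep_merge(DEFAULT_CONFIG, PROFILES[profile])
    cfg = _deep_merge(cfg, user)
    return cfg


def resolve_config(cfg: dict) -> dict:
    """Attach reproducibility metadata to a config."""
    out = copy.deepcopy(cfg)
    out["_meta"] = {
        "bpfuse_version": bpfuse.__version__,
        "python": platform.python_version(),
    }
    return out


def write_resolved_config(cfg: dict, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(resolve_config(cfg), fh, sort_keys=False)
    return path
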