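"""Run configuration and manifest.

A run is configured by a flat YAML file whose keys split into three groups:
estimator hyperparameters (anything `DTIPredictor` accepts), synthetic-data
settings (`data.*`), and run settings (seed, output paths, fold counts).  The
manifest written at the end of a run records the resolved configuration, the
seed, a checksum of the input files and the metric report — enough to re-run
the experiment bit-compatibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from .model import DTIPredictor
from .synthetic import SyntheticConfig

__all__ = ["load_config", "split_config", "RunManifest", "file_checksum"]

_ESTIMATOR_KEYS = set(DTIPredictor().get_params())
_DATA_KEYS = {f.name for f in dataclasses.fields(SyntheticConfig)}
_RUN_KEYS = {"seed", "k_folds", "rotation", "scenario", "fraction", "out_dir",
             "p_at", "n_iter", "seeds"}


def load_config(path) -> dict:
    """Load a flat YAML config; unknown keys raise with the valid key list."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    valid = _ESTIMATOR_KEYS | {f"data.{k}" for k in _DATA_KEYS} | _RUN_KEYS
    unknown = [k for k in raw if k not in valid]
    if unknown:
        raise ValueError(
            f"{path}: invalid config key(s) {unknown}; valid keys: "
            f"{sorted(valid)}")
    return raw


def split_config(raw: dict) -> tuple[dict, dict, dict]:
    """(estimator kwargs, synthetic-data kwargs, run settings)."""
    est = {k: v for k, v in raw.items() if k in _ESTIMATOR_KEYS}
    data = {k[len("data."):]: v for k, v in raw.items()
            if k.startswith("data.")}
    run = {k: v for k, v in raw.items() if k in _RUN_KEYS}
    return est, data, run


def file_checksum(paths) -> str:
    digest = hashlib.sha256()
    for p in sorted(str(p) for p in paths):
        digest.update(Path(p).read_bytes())
    return digest.hexdigest()[:16]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


class RunManifest:
    """Reproducibility record of one run, written atomically at run end."""

    def __init__(self, config: dict, seed: int):
        self.payload = {
            "config": config,
            "seed": int(seed),
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def record(self, **items):
        self.payload.update(items)

    def write(self, path) -> Path:
        path = Path(path)
        self.payload["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.payload, indent=1, sort_keys=True,
                                  cls=_NumpyEncoder))
        tmp.replace(path)
        return path
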