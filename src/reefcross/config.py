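"""Run configuration: a flat YAML file of ``key: value`` pairs (nested
sections allowed) that can pre-set any CLI flag, plus a run manifest that
records the seed and effective parameters for reproducibility."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

__all__ = ["load_config", "write_manifest", "setup_logging"]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_manifest(out_dir: str | Path, **params) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(params, fh, indent=1, sort_keys=True, default=str)
    return path


def setup_logging(level: str = "INFO") -> logging.Logger:
    logger = logging.getLogger("reefcross")
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())
    return logger
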