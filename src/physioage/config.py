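"""Run configuration: one YAML file, every parameter addressable by dotted key."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import yaml

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "clean": {"trait_frac": 0.8, "indiv_frac": 0.8},
    "bins": {"width": 5.0},
    "model": {"family": "bin_classifier_forest", "use_lda": True, "k": None},
    "ensemble": {"m": 10_000, "rescale_mode": "rescale", "trim_bins": 1},
    "mortality": {"reps": 10_000, "window": 0.5, "alpha": 0.05, "follow_up": 2.5},
    "ranking": {"alpha": 0.05, "splits_per_trait": 500},
    "simulate": {},
    "stages": ["clean", "fit", "par", "mortality", "rank"],
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


class RunConfig:
    """Nested mapping with dotted-key access, e.g. cfg['mortality.window']."""

    def __init__(self, data: dict | None = None):
        self.data = _merge(DEFAULTS, data or {})

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        known = set(DEFAULTS)
        unknown = set(loaded) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        return cls(loaded)

    def __getitem__(self, dotted: str) -> Any:
        node: Any = self.data
        for part in dotted.split("."):
            if not isinstance(node, dict) or part not in node:
                raise KeyError(f"unknown config key {dotted!r}")
            node = node[part]
        return node

    def get(self, dotted: str, default: Any = None) -> Any:
        try:
            return self[dotted]
        except KeyError:
            return default

    def set(self, dotted: str, value: Any) -> None:
        parts = dotted.split(".")
        node = self.data
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value


def setup_logging(log_path: str | Path | None = None,
                  level: int = logging.INFO) -> logging.Logger:
    """Timestamped text log shared by every pipeline stage."""
    logger = logging.getLogger("physioage")
    logger.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    if log_path is not None:
        fh = logging.FileHandler(log_path)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger
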