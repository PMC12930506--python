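"""YAML configuration loading and validation.

A configuration is a plain nested dict with the sections defined in the
packaged ``configs/defaults.yaml``; shipped benchmark configs extend the
defaults via an ``extends`` key.  :func:`load_config` accepts a file path
or the bare name of a packaged config (``defaults``,
``benchmark_endpoint``, ``benchmark_timelapse``, ``benchmark_central``).
"""

from __future__ import annotations

import importlib.resources as resources
from pathlib import Path

import numpy as np
import yaml

from .signal_model import GateParams, RnaSpecies

__all__ = [
    "load_config",
    "gate_from_config",
    "species_from_config",
    "radius_grid_from_config",
    "validate_config",
]

_SECTIONS = {
    "version",
    "extends",
    "seed",
    "gate",
    "species",
    "layout",
    "simulate",
    "render",
    "analysis",
    "calibration",
}


def _packaged(name: str) -> dict:
    ref = resources.files("mimicomm").joinpath(f"configs/{name}.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source: str | Path | dict | None = None) -> dict:
    """Load, resolve inheritance, and validate a configuration."""
    if source is None:
        cfg = _packaged("defaults")
    elif isinstance(source, dict):
        cfg = dict(source)
    else:
        p = Path(source)
        if p.exists():
            with open(p) as fh:
                cfg = yaml.safe_load(fh)
        else:
            cfg = _packaged(str(source))
    parent = cfg.pop("extends", None)
    if parent:
        cfg = _deep_merge(load_config(parent), cfg)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    unknown = set(cfg) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    for key in ("gate", "species", "layout", "simulate"):
        if key not in cfg:
            raise ValueError(f"config missing required section {key!r}")
    # constructing the parameter objects runs their invariant checks
    gate_from_config(cfg)
    species_from_config(cfg)


def gate_from_config(cfg: dict) -> GateParams:
    return GateParams(**cfg["gate"])


def species_from_config(cfg: dict) -> tuple[RnaSpecies, RnaSpecies]:
    sp = cfg["species"]
    star = RnaSpecies(name="STAR", **sp["STAR"])
    trig = RnaSpecies(name="trigger", **sp["trigger"])
    return star, trig


def radius_grid_from_config(cfg: dict) -> np.ndarray:
    start, stop, step = cfg["analysis"]["radius_grid"]
    return np.arange(start, stop + 0.5 * step, step)
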