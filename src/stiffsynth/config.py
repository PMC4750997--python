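"""Run configuration: schema, validation, serialization.

A run config is a flat YAML mapping.  Unknown keys are rejected up front so
typos fail loudly instead of silently running defaults.  Angles are degrees
in the file (and everywhere user-facing); they are converted to radians at
the model boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import yaml

from .arm import ArmModel
from .synergy import SynergyBasis

__all__ = ["RunConfig", "ConfigError", "load_config", "arm_from_config", "format_float"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    """Validated run parameters (degrees and plain lists; see field comments).

    Arm fields default to the nominal six-muscle arm when omitted.
    """

    link_lengths: list[float] = field(default_factory=lambda: [1.0, 1.0])
    moment_arms: list[list[float]] | None = None  # joints x muscles
    f_max: list[float] | None = None
    alpha: float = 1.0
    joint_limits_deg: list[list[float]] | None = None  # per joint [min, max]

    shapes: list[float] = field(default_factory=lambda: [2.0])  # ellipse condition numbers
    orientation_deg: float = 0.0
    scale: float | str = "auto"  # desired-stiffness size, or "auto"
    orientation_step_deg: float = 5.0
    grid: list[int] = field(default_factory=lambda: [25, 25])

    ratio_min: float = 0.1
    ratio_max: float = 10.0
    n_ratios: int = 200
    base_total: float = 0.5
    synergies: dict[str, list[list[float]]] = field(default_factory=dict)

    endpoint: list[float] | None = None  # workspace position; IK if posture absent
    posture_deg: list[float] | None = None
    ik_branch: str = "elbow_positive"

    seed: int = 0
    verbosity: str = "INFO"

    def echo(self) -> dict[str, Any]:
        return asdict(self)


_KNOWN = set(RunConfig.__dataclass_fields__)


def load_config(path_or_mapping) -> RunConfig:
    """Load and validate a config from a YAML path or an in-memory mapping."""
    if isinstance(path_or_mapping, dict):
        raw = dict(path_or_mapping)
    else:
        with open(path_or_mapping) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
    unknown = sorted(set(raw) - _KNOWN)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    cfg = RunConfig(**raw)
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    if any(s < 1.0 for s in cfg.shapes):
        raise ConfigError("ellipse shapes (condition numbers) must be >= 1")
    if cfg.scale != "auto" and (not isinstance(cfg.scale, (int, float)) or cfg.scale <= 0):
        raise ConfigError('scale must be a positive number or "auto"')
    n = 180.0 / cfg.orientation_step_deg
    if abs(n - round(n)) > 1e-9:
        raise ConfigError("orientation_step_deg must divide 180")
    if len(cfg.grid) != 2 or any(g < 2 for g in cfg.grid):
        raise ConfigError("grid must be [n1, n2] with entries >= 2")
    if not (0 < cfg.ratio_min < cfg.ratio_max):
        raise ConfigError("need 0 < ratio_min < ratio_max")
    if cfg.n_ratios < 2:
        raise ConfigError("n_ratios must be >= 2")
    if cfg.ik_branch not in ("elbow_positive", "elbow_negative"):
        raise ConfigError("ik_branch must be elbow_positive or elbow_negative")
    for name, W in cfg.synergies.items():
        arr = np.asarray(W, dtype=float)
        if arr.ndim != 2 or np.any(arr < 0):
            raise ConfigError(f"synergy {name!r} must be a nonnegative muscles x synergies table")


def arm_from_config(cfg: RunConfig) -> ArmModel:
    kwargs: dict[str, Any] = {"link_lengths": np.asarray(cfg.link_lengths, dtype=float), "alpha": cfg.alpha}
    if cfg.moment_arms is not None:
        kwargs["moment_arms"] = np.asarray(cfg.moment_arms, dtype=float)
    if cfg.f_max is not None:
        kwargs["f_max"] = np.asarray(cfg.f_max, dtype=float)
    if cfg.joint_limits_deg is not None:
        kwargs["joint_limits"] = np.asarray(
            [[math.radians(v) for v in row] for row in cfg.joint_limits_deg]
        )
    return ArmModel(**kwargs)


def synergy_from_config(cfg: RunConfig, name: str) -> SynergyBasis:
    if name not in cfg.synergies:
        raise ConfigError(f"synergy {name!r} not defined in config")
    W = np.asarray(cfg.synergies[name], dtype=float)
    return SynergyBasis(W=W, names=tuple(f"{name}_{i}" for i in range(W.shape[1])))


def format_float(x: float) -> float:
    """Round-trip a float through 12 significant digits for stable output."""
    return float(f"{x:.12g}")


def dump_json(obj: Any, path) -> None:
    """Write a JSON summary with floats fixed at 12 significant digits."""

    def walk(v):
        if isinstance(v, float):
            return format_float(v)
        if isinstance(v, dict):
            return {k: walk(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [walk(x) for x in v]
        if isinstance(v, np.ndarray):
            return [walk(float(x)) for x in v.ravel()]
        if isinstance(v, (np.floating,)):
            return format_float(float(v))
        if isinstance(v, (np.integer,)):
            return int(v)
        return v

    with open(path, "w") as fh:
        json.dump(walk(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
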