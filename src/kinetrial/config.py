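"""Run configuration: nested, schema-checked, YAML/JSON round-trippable.

A :class:`RunConfig` gathers every knob of the pipeline in named sections
(sim, agent, ode, solver, de, fit, stats) plus a single global seed from
which each stochastic stage derives its own stream.  Loading rejects
unknown keys with the offending path, fills defaults for everything else,
and ``load_config(write_config(cfg)) == cfg``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from .agent import AgentConfig
from .cohort_sim import SimConfig
from .errors import ConfigError
from .fitting import DEConfig
from .kinetics import ODEParams
from .rk_core import IntegratorConfig

__all__ = ["RunConfig", "FitOptions", "StatsOptions", "load_config", "write_config"]


@dataclass(frozen=True)
class FitOptions:
    split: float = 0.7
    outcomes: tuple[str, ...] = ("vocab", "anxiety")
    predictor: str = "rk"
    n_steps_per_week: int = 4
    bootstrap: int = 200

    def __post_init__(self):
        if not (0.0 < self.split < 1.0):
            raise ConfigError("fit.split must lie in (0, 1)")
        if self.predictor not in ("rk", "exact"):
            raise ConfigError("fit.predictor must be 'rk' or 'exact'")


@dataclass(frozen=True)
class StatsOptions:
    z_threshold: float = 3.29
    t_variant: str = "pooled"
    anova_variant: str = "mixed"

    def __post_init__(self):
        if self.t_variant not in ("pooled", "welch"):
            raise ConfigError("stats.t_variant must be 'pooled' or 'welch'")
        if self.anova_variant not in ("mixed", "between"):
            raise ConfigError("stats.anova_variant must be 'mixed' or 'between'")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    outdir: str = "runs"
    sim: SimConfig = field(default_factory=SimConfig)
    de: DEConfig = field(default_factory=DEConfig)
    fit: FitOptions = field(default_factory=FitOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(to_plain_dict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def to_plain_dict(obj):
    """Recursively convert dataclasses/tuples/numpy scalars to JSON-safe types."""
    if is_dataclass(obj):
        return {f.name: to_plain_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: to_plain_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_plain_dict(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return obj.value  # enums
    return obj


_TUPLE_FIELDS = {"outcomes", "bounds", "breakpoints", "I_levels", "S_levels"}


def _build(cls, data: dict, path: str):
    """Construct dataclass ``cls`` from a dict, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"section '{path}' must be a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown key '{path}.{sorted(unknown)[0]}'")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        sub_cls = _nested_dataclass(f)
        if sub_cls is not None:
            kwargs[name] = _build(sub_cls, value, f"{path}.{name}")
        elif name in _TUPLE_FIELDS and isinstance(value, list):
            kwargs[name] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        elif isinstance(value, dict) and isinstance(_default_of(cls, name), dict):
            merged = {**_default_of(cls, name)}
            for k, v in value.items():
                if isinstance(v, dict) and isinstance(merged.get(k), dict):
                    merged[k] = {**merged[k], **{kk: tuple(vv) if isinstance(vv, list) else vv for kk, vv in v.items()}}
                else:
                    merged[k] = v
            kwargs[name] = merged
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{path}': {exc}") from exc


def _nested_dataclass(f):
    mapping = {
        "sim": SimConfig, "de": DEConfig, "fit": FitOptions, "stats": StatsOptions,
        "params": ODEParams, "agent": AgentConfig, "solver": IntegratorConfig,
    }
    return mapping.get(f.name)


def _default_of(cls, name):
    f = next(f for f in fields(cls) if f.name == name)
    if f.default is not dataclasses.MISSING:
        return f.default
    if f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
        return f.default_factory()
    return None


def load_config(path) -> RunConfig:
    """Parse and validate a YAML or JSON run configuration file.

    An empty file yields the full default configuration.  Unknown keys are
    rejected with the offending key path; invalid values raise
    :class:`ConfigError` naming the section.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    return _build(RunConfig, data, "run")


def write_config(config: RunConfig, path) -> Path:
    """Serialize a RunConfig to YAML; inverse of :func:`load_config`."""
    path = Path(path)
    path.write_text(yaml.safe_dump(to_plain_dict(config), sort_keys=True))
    return path
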