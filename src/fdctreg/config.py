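"""Flat ``key = value`` text configuration shared by all CLI commands.

Unknown keys are rejected so typos fail loudly.  Values are parsed as int,
float, tuple of numbers (comma- or space-separated) or string, matching the
target dataclass field.  CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .errors import FdctRegError
from .metric import MetricConfig
from .optimize import OptimizerConfig
from .phantom import PhantomSpec
from .registration import RegistrationConfig

__all__ = ["read_config_file", "registration_config_from_dict", "phantom_spec_from_dict"]


def read_config_file(path) -> dict[str, str]:
    values: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FdctRegError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        values[key] = value
    return values


def _coerce(value: str, like) -> object:
    if isinstance(like, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(like, int):
        return int(value)
    if isinstance(like, float):
        return float(value)
    if isinstance(like, tuple):
        parts = value.replace(",", " ").split()
        elem = like[0] if like else 1.0
        return tuple(int(p) if isinstance(elem, int) else float(p) for p in parts)
    return value


def _apply(values: dict[str, str], targets: list) -> None:
    """Assign each key to the first target dataclass that has that field."""
    for key, raw in values.items():
        for target in targets:
            fields = {f.name: getattr(target, f.name) for f in dataclasses.fields(target)
                      if not dataclasses.is_dataclass(getattr(target, f.name))}
            if key in fields:
                setattr(target, key, _coerce(raw, fields[key]))
                break
        else:
            raise FdctRegError(f"unknown configuration key {key!r}")


def registration_config_from_dict(values: dict[str, str]) -> RegistrationConfig:
    cfg = RegistrationConfig()
    _apply(values, [cfg, cfg.metric, cfg.optimizer])
    # re-validate after overrides
    MetricConfig(**dataclasses.asdict(cfg.metric))
    OptimizerConfig(**dataclasses.asdict(cfg.optimizer))
    return RegistrationConfig(metric=cfg.metric, optimizer=cfg.optimizer, levels=cfg.levels,
                              shrink_factors=cfg.shrink_factors,
                              smoothing_sigmas_mm=cfg.smoothing_sigmas_mm, seed=cfg.seed)


def phantom_spec_from_dict(values: dict[str, str]) -> PhantomSpec:
    spec = PhantomSpec()
    _apply(values, [spec])
    return PhantomSpec(**dataclasses.asdict(spec))
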