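"""Flat, auditable pipeline configuration.

Every classifier threshold is a tuning knob that a reviewer may want to see
and override, so the configuration round-trips through a flat
``key = value`` text format and supports ``--set key=value`` overrides.
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Tuple, Union

from .acg import AcgConfig
from .ddh import DdhConfig

__all__ = ["PipelineConfig", "ConfigError", "CONSENSUS_POLICIES"]

CONSENSUS_POLICIES = ("acg-primary", "ddh-primary", "strict")


class ConfigError(ValueError):
    """Raised for malformed configuration files or unknown keys."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the classification pipeline."""

    acg: AcgConfig = field(default_factory=AcgConfig)
    ddh: DdhConfig = field(default_factory=DdhConfig)
    consensus_policy: str = "acg-primary"
    min_spikes: int = 500
    min_duration: float = 180.0
    rate_range: Tuple[float, float] = (0.5, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.consensus_policy not in CONSENSUS_POLICIES:
            raise ConfigError(
                f"unknown consensus policy {self.consensus_policy!r}; "
                f"choose from {CONSENSUS_POLICIES}"
            )
        for name, obj in (("acg", self.acg), ("ddh", self.ddh)):
            for f in fields(obj):
                v = getattr(obj, f.name)
                if isinstance(v, (int, float)) and not isinstance(v, bool) and v <= 0:
                    raise ConfigError(f"{name}.{f.name} must be positive, got {v}")

    # -- flat key space ----------------------------------------------------

    def to_flat(self) -> dict:
        """Flatten to ``section.key -> value`` plus top-level keys."""
        out = {}
        for section, obj in (("acg", self.acg), ("ddh", self.ddh)):
            for f in fields(obj):
                v = getattr(obj, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                out[f"{section}.{f.name}"] = v
        out["consensus_policy"] = self.consensus_policy
        out["min_spikes"] = self.min_spikes
        out["min_duration"] = self.min_duration
        out["rate_range"] = ",".join(str(x) for x in self.rate_range)
        out["seed"] = self.seed
        return out

    def with_overrides(self, pairs: Iterable[str]) -> "PipelineConfig":
        """Apply ``key=value`` override strings and return a new config."""
        acg_kw, ddh_kw, top_kw = {}, {}, {}
        for pair in pairs:
            if "=" not in pair:
                raise ConfigError(f"override must look like key=value, got {pair!r}")
            key, raw = (s.strip() for s in pair.split("=", 1))
            if key.startswith("acg."):
                _set_field(acg_kw, AcgConfig, key[4:], raw, key)
            elif key.startswith("ddh."):
                _set_field(ddh_kw, DdhConfig, key[4:], raw, key)
            elif key in ("consensus_policy",):
                top_kw[key] = raw
            elif key in ("min_spikes", "seed"):
                top_kw[key] = int(raw)
            elif key == "min_duration":
                top_kw[key] = float(raw)
            elif key == "rate_range":
                top_kw[key] = _parse_tuple(raw, float)
            else:
                raise ConfigError(f"unknown configuration key {key!r}")
        return dataclasses.replace(
            self,
            acg=dataclasses.replace(self.acg, **acg_kw),
            ddh=dataclasses.replace(self.ddh, **ddh_kw),
            **top_kw,
        )

    # -- file round-trip ---------------------------------------------------

    def write(self, path: Union[str, Path]) -> None:
        lines = [f"{k} = {v}" for k, v in self.to_flat().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: Union[str, Path]) -> "PipelineConfig":
        pairs = []
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{ln}: expected 'key = value', got {line!r}")
            pairs.append(line)
        return cls().with_overrides(pairs)


def _parse_tuple(raw: str, cast):
    return tuple(cast(x) for x in raw.split(","))


def _set_field(kwargs: dict, cls, name: str, raw: str, full_key: str) -> None:
    for f in fields(cls):
        if f.name == name:
            if f.type.startswith("Tuple") or isinstance(getattr(cls(), name), tuple):
                proto = getattr(cls(), name)
                cast = int if all(isinstance(x, int) for x in proto) else float
                kwargs[name] = _parse_tuple(raw, cast)
            elif isinstance(getattr(cls(), name), bool):
                kwargs[name] = raw.lower() in ("1", "true", "yes")
            elif isinstance(getattr(cls(), name), int):
                kwargs[name] = int(raw)
            else:
                kwargs[name] = float(raw)
            return
    raise ConfigError(f"unknown configuration key {full_key!r}")
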