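"""Run configuration: YAML loading with strict validation.

A run config nests the window, model, training, split and provider
settings.  Unknown keys are rejected (typos should fail loudly, not
silently fall back to defaults), constraint violations raise at load time,
and the fully resolved config is serialised next to every artifact a
command writes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dataset import SplitSpec
from .network import ModelConfig
from .training import TrainSpec
from .windowing import WindowConfig

__all__ = ["ProviderConfig", "RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class ProviderConfig:
    esm: str = "synthetic"  # synthetic | esm2
    pt: str = "synthetic"  # synthetic | prottrans
    synthetic_esm_dim: int = 32
    synthetic_pt_dim: int = 24

    def __post_init__(self):
        if self.esm not in ("synthetic", "esm2"):
            raise ValueError(f"unknown esm provider {self.esm!r}")
        if self.pt not in ("synthetic", "prottrans"):
            raise ValueError(f"unknown pt provider {self.pt!r}")


@dataclass(frozen=True)
class RunConfig:
    window: WindowConfig = field(default_factory=WindowConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainSpec = field(default_factory=TrainSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    provider: ProviderConfig = field(default_factory=ProviderConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


_SECTIONS = {
    "window": WindowConfig,
    "model": ModelConfig,
    "train": TrainSpec,
    "split": SplitSpec,
    "provider": ProviderConfig,
}

_TUPLE_KEYS = {"conv_kernels", "conv_channels", "head_widths", "seq_len_range"}


def _build_section(cls, raw: dict, section: str):
    if not isinstance(raw, dict):
        raise ValueError(f"config section {section!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    coerced = {k: tuple(v) if k in _TUPLE_KEYS and isinstance(v, list) else v
               for k, v in raw.items()}
    return cls(**coerced)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config; missing keys take the package defaults.

    ``overrides`` (e.g. parsed CLI flags) take precedence over file values,
    which take precedence over defaults.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        raw = loaded
    for section, values in (overrides or {}).items():
        raw.setdefault(section, {})
        if isinstance(values, dict):
            raw[section].update(values)
        else:
            raw[section] = values
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    sections = {
        name: _build_section(cls, raw.get(name, {}), name)
        for name, cls in _SECTIONS.items()
    }
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ValueError("seed must be an integer")
    return RunConfig(seed=seed, **sections)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Serialise the resolved config (JSON) next to an output artifact."""
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, default=str)
        fh.write("\n")
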