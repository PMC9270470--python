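"""Run configuration: YAML-backed defaults for the CLI."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from cavorient.errors import ValueRangeError

DEFAULTS = {
    "iterations": 1000,
    "conf": 0.95,
    "seed": 0,
    "n_boot": 1000,
}


@dataclass(frozen=True)
class RunConfig:
    iterations: int = 1000
    conf: float = 0.95
    seed: int = 0
    n_boot: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.conf < 1.0):
            raise ValueRangeError(f"conf must be in (0, 1), got {self.conf}")
        if self.iterations < 1:
            raise ValueRangeError("iterations must be >= 1")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Merge DEFAULTS <- YAML file (if given) <- keyword overrides."""
    values = dict(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(DEFAULTS)
        if unknown:
            raise ValueRangeError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def file_digest(path: str | Path) -> str:
    """Short sha256 digest of an input file, for the run log."""
    h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return h[:12]
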