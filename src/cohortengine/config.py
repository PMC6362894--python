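"""Run configuration loaded from a YAML key/value file.

Declares the race-code registry (three- or four-group layouts), the census
interval ``y``, the sex ratio at birth, and the output rounding mode.  Every
field has the package default so an empty file (or no file) is valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .panel import RACE_REGISTRY_FOUR, RACE_REGISTRY_THREE

__all__ = ["RunSettings", "load_config"]

_REGISTRIES = {"four": RACE_REGISTRY_FOUR, "three": RACE_REGISTRY_THREE}


@dataclass
class RunSettings:
    interval: int = 5
    srb: float = 1.05
    rounding: str = "none"            # none | nearest
    race_registry: str = "four"       # four | three
    blend_mode: str = "blended"
    min_len: int = 4

    def __post_init__(self):
        if self.rounding not in {"none", "nearest"}:
            raise ValueError(f"rounding must be none|nearest, got {self.rounding!r}")
        if self.race_registry not in _REGISTRIES:
            raise ValueError(
                f"race_registry must be one of {sorted(_REGISTRIES)}, got "
                f"{self.race_registry!r}"
            )

    @property
    def races(self) -> Mapping[int, str]:
        return _REGISTRIES[self.race_registry]

    def as_dict(self) -> dict:
        return {
            "interval": self.interval,
            "srb": self.srb,
            "rounding": self.rounding,
            "race_registry": self.race_registry,
            "blend_mode": self.blend_mode,
            "min_len": self.min_len,
        }


def load_config(path: str | Path | None) -> RunSettings:
    if path is None:
        return RunSettings()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunSettings.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; known: {sorted(known)}")
    return RunSettings(**raw)
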