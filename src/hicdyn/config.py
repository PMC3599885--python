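"""Run configuration: one serializable object holding every analysis knob."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Analysis parameters; serializable to a single YAML file.

    ``digest()`` gives a short content hash that outputs embed so any table
    can be traced back to the exact configuration that produced it.
    """

    window: int = 1_000_000
    hot_threshold: float = 30.0  # percent
    cold_threshold: float = 0.5  # percent
    top_n: int = 10
    frequency_thresholds: tuple[float, ...] = (1, 5, 10, 20, 30, 40, 50, 60)
    ratio_cut: float = 2.0
    z_cut: float = 1.0
    mode: str = "strict"  # strict | relaxed
    flank: int = 5000
    log_base: float = 2.0
    pseudocount: float = 1.0
    test: str = "t"  # t | mann-whitney
    expected_mode: str = "distance"  # distance | uniform
    dedup: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frequency_thresholds"] = list(d["frequency_thresholds"])
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "frequency_thresholds" in data:
            data["frequency_thresholds"] = tuple(data["frequency_thresholds"])
        return cls(**data)
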