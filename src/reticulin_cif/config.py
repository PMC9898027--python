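"""Run configuration: one versioned mapping, hashed into every output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import InvalidArgumentError


@dataclass
class RunConfig:
    tile_size: int = 512
    stride: int = 256
    fat_max: float = 0.50
    bone_max: float = 0.01
    vessel_max: float = 0.10
    bin_edges: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    hotspot_threshold: float = 0.5
    input_size: int = 32
    rounds: int = 3
    pairs_per_round: int = 700
    epochs: int = 6
    learning_rate: float = 2e-3
    concordance: float = 0.884
    n_annotators: int = 3
    seed: int = 0
    microns_per_pixel: float = 0.22  # recorded as metadata only

    def __post_init__(self) -> None:
        if self.tile_size <= 0 or self.stride <= 0:
            raise InvalidArgumentError("tile_size and stride must be positive")
        for name in ("fat_max", "bone_max", "vessel_max", "hotspot_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name} must lie in [0, 1]")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["bin_edges"] = list(d["bin_edges"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "bin_edges" in d:
            d["bin_edges"] = tuple(d["bin_edges"])
        return cls(**d)
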