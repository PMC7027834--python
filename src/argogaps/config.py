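"""Run configuration: every analysis threshold in one serializable object.

Defaults are the reference analysis settings: years 2005-2016, gap quantile
q = 0.20 (lowest quintile of positive profile counts), persistence
threshold 0.80, minimum coldspot size 25 one-degree cells, 8-connectivity
with longitude wrap, areas in km².
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class RunConfig:
    years: tuple[int, int] = (2005, 2016)   # inclusive range
    q: float = 0.20
    persistence_threshold: float = 0.80
    min_cells: int = 25
    connectivity: int = 8
    wrap: bool = True
    area_mode: str = "km2"                  # "km2" | "cells" (debug)
    composite_mode: str = "all_taxa"        # | "present_taxa"
    seed: int = 0
    workdir: str = "runs/demo"
    scenario: dict = field(default_factory=dict)   # synth-stage overrides
    inputs: dict = field(default_factory=dict)     # external input paths
    render: bool = False
    projection: str = "mollweide"

    def __post_init__(self):
        self.years = tuple(int(y) for y in self.years)
        if len(self.years) != 2 or self.years[0] > self.years[1]:
            raise ValueError("years must be an inclusive (start, end) pair")
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.area_mode not in ("km2", "cells"):
            raise ValueError("area_mode must be 'km2' or 'cells'")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
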