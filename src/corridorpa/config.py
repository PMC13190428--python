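"""Run configuration: every stage reads its parameters from here.

A serialised copy is written beside the outputs of each run for
provenance; every defaulted parameter is logged once at run start.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import yaml

from .synthetic import CorridorConfig, DEFAULT_SPEED_BANDS
from .trajectories import DEFAULT_MIN_DURATION, DEFAULT_TELEPORT_LIMIT


@dataclass
class RunConfig:
    seed: int = 0
    corridor: CorridorConfig = field(default_factory=CorridorConfig)
    # cleaning
    min_duration: float = DEFAULT_MIN_DURATION
    speed_bands: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_SPEED_BANDS.items()})
    teleport_limit: float = DEFAULT_TELEPORT_LIMIT
    intensity_mode: str = "apportion"
    # screening
    r_cut: float = 0.8
    evr_cut: float = 0.85
    # driver models
    n_estimators: int = 300
    max_depth: int = 4
    learning_rate: float = 0.05
    cv_folds: int = 5
    # spatial stats
    weights_scheme: str = "queen"
    knn_k: int = 8
    permutations: int = 999
    county_block: int = 4
    mgwr_covariates: int = 3      # top factors per activity entering MGWR
    # zoning
    theta: float = 0.2
    k_clusters: int = 4
    jenks_classes: int = 2
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["speed_bands"] = {k: list(v) for k, v in d["speed_bands"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        corridor = CorridorConfig(**d.pop("corridor", {}))
        bands = {k: tuple(v) for k, v in d.pop("speed_bands",
                 {a: list(b) for a, b in DEFAULT_SPEED_BANDS.items()}).items()}
        return cls(corridor=corridor, speed_bands=bands, **d)
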