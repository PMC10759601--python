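"""Pipeline configuration: all thresholds, grids and seeds in one place.

Defaults reproduce the study settings: a 9-value binarization grid
0.00-0.40 in steps of 0.05, operating threshold 0.20, augmentation that
perturbs 5 ROI pairs with uniform noise in (0.0, 0.3), 10-fold grid-search
cross-validation, SpeCo swept over k in 2..5 and majority thresholds
{0.90, 0.95}, and the top 100 RLF pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .datamodel import ConnectomlError, stage_seed

FULL_TAU_GRID = tuple(round(0.05 * i, 2) for i in range(9))  # 0.00 .. 0.40
COMPARABLE_TAU_GRID = FULL_TAU_GRID[:7]  # 0.00 .. 0.30, beyond which isolates appear


@dataclass
class PipelineConfig:
    tau_grid: tuple[float, ...] = FULL_TAU_GRID
    selected_tau: float = 0.20
    # augmentation
    n_pairs: int = 5
    noise_lo: float = 0.0
    noise_hi: float = 0.3
    balance_ratio: float = 1.0
    # evaluation
    folds: int = 10
    # biomarker discovery
    speco_k_range: tuple[int, ...] = (2, 3, 4, 5)
    speco_theta_range: tuple[float, ...] = (0.90, 0.95)
    rlf_top_m: int = 100
    # fisher cap for |r| = 1
    z_max: float = 3.8002
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.tau_grid) == 0:
            raise ConnectomlError("tau_grid must be non-empty")
        if not all(0.0 <= t < 1.0 for t in self.tau_grid):
            raise ConnectomlError("thresholds must lie in [0, 1)")
        if self.selected_tau not in self.tau_grid:
            raise ConnectomlError("selected_tau must be a member of tau_grid")
        if not (0.0 <= self.noise_lo < self.noise_hi):
            raise ConnectomlError("need 0 <= noise_lo < noise_hi")
        if self.n_pairs < 1 or self.folds < 2:
            raise ConnectomlError("n_pairs >= 1 and folds >= 2 required")

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("tau_grid", "speco_k_range", "speco_theta_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
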