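"""Run configuration: every tunable of the pipeline in one YAML-serialisable
object, with defaults matching the study protocol (21-mer windows, 50%
identity filter, 2:1 negatives, chi-squared cutoff 34.3, 30 resampling
repeats)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .mdd import CHI2_THRESHOLD_DEFAULT, DEFAULT_GROUPS, GroupMap


@dataclass
class RunConfig:
    residue: str = "K"
    n: int = 10  # window half-width
    identity_threshold: float = 0.5
    neg_ratio: int = 2
    repeats: int = 30
    folds: int = 5
    chi2_threshold: float = CHI2_THRESHOLD_DEFAULT
    max_cluster_size: int = 30
    pseudocount: float = 0.5
    split_criterion: str = "pair"  # or "sum"
    split_mode: str = "binary"  # or "five_way"
    groups: dict = field(default_factory=lambda: {
        name: list(aas) for name, aas in DEFAULT_GROUPS.items()
    })
    c_exponents: list = field(default_factory=lambda: list(range(-5, 16, 2)))
    gamma_exponents: list = field(default_factory=lambda: list(range(-15, 4, 2)))
    seed: int = 0

    def group_map(self) -> GroupMap:
        return GroupMap.from_groups(self.groups)

    @property
    def c_grid(self) -> tuple[float, ...]:
        return tuple(2.0 ** e for e in self.c_exponents)

    @property
    def gamma_grid(self) -> tuple[float, ...]:
        return tuple(2.0 ** e for e in self.gamma_exponents)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = np.random.SeedSequence(
            [self.seed, sum(ord(c) for c in stage) + len(stage) * 1000]
        )
        return int(h.generate_state(1)[0] % (2**31 - 1))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
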