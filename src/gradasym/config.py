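"""Pipeline configuration.

A single declarative object carries every tunable of the pipeline:
how many gradients are computed (10) versus analyzed (3), the row
sparsity used before building the affinity (top 10% of connections),
the diffusion-map anisotropy alpha (0.5), subject exclusion rules,
age-group boundaries, and multiple-testing settings.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParameterError

#: Half-open age-group boundaries in years: child [5, 12), adolescent
#: [12, 18), adult [18, 40].
DEFAULT_AGE_BOUNDARIES: tuple[float, float, float, float] = (5.0, 12.0, 18.0, 40.0)

AGE_GROUP_LABELS = ("child", "adolescent", "adult")


@dataclass(frozen=True)
class MultipleTesting:
    """Multiplicity control settings: BH-FDR level and post-hoc Bonferroni k."""

    fdr_q: float = 0.05
    posthoc_bonferroni_k: int = 3


@dataclass(frozen=True)
class PipelineConfig:
    n_gradients_computed: int = 10
    n_gradients_analyzed: int = 3
    sparsity_density: float = 0.10
    alpha: float = 0.5
    diffusion_time: float = 0.0  # 0 = multiscale scaling lambda/(1-lambda)
    fd_threshold_mm: float = 0.3
    max_age_years: float = 40.0
    min_fiq: float = 70.0
    age_group_boundaries: tuple[float, float, float, float] = DEFAULT_AGE_BOUNDARIES
    gsr: bool = False
    random_seed: int = 0
    multiple_testing: MultipleTesting = field(default_factory=MultipleTesting)

    def __post_init__(self) -> None:
        if not (0.0 < self.sparsity_density <= 1.0):
            raise ParameterError(
                f"sparsity_density must be in (0, 1], got {self.sparsity_density}"
            )
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_gradients_analyzed > self.n_gradients_computed:
            raise ParameterError(
                "n_gradients_analyzed cannot exceed n_gradients_computed "
                f"({self.n_gradients_analyzed} > {self.n_gradients_computed})"
            )
        if len(self.age_group_boundaries) != 4 or any(
            a >= b for a, b in zip(self.age_group_boundaries, self.age_group_boundaries[1:])
        ):
            raise ParameterError(
                f"age_group_boundaries must be 4 increasing values, got {self.age_group_boundaries}"
            )

    def age_group_of(self, age: float) -> str:
        """Assign an age group; intervals are half-open [lo, hi) except the last, closed."""
        b = self.age_group_boundaries
        if age < b[0] or age > b[3]:
            return "out_of_range"
        if age < b[1]:
            return "child"
        if age < b[2]:
            return "adolescent"
        return "adult"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_group_boundaries"] = list(self.age_group_boundaries)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "multiple_testing" in d and isinstance(d["multiple_testing"], dict):
            d["multiple_testing"] = MultipleTesting(**d["multiple_testing"])
        if "age_group_boundaries" in d:
            d["age_group_boundaries"] = tuple(d["age_group_boundaries"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
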