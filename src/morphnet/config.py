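"""Pipeline configuration: every tunable parameter in one audited place.

One global seed is expanded into per-stage seeds through a documented
counter scheme (``SeedSequence(seed, stage_index)``), so stages are
individually reproducible and never share random streams.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: Pipeline stages in execution order; the index is the seed counter.
STAGES = (
    "simulate",
    "construct",
    "metrics",
    "compare",
    "nbs",
    "classify",
    "correlate",
)


class ConfigError(ValueError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived integer seed for one stage (< 2**31)."""
    try:
        idx = STAGES.index(stage)
    except ValueError as exc:
        raise ConfigError(f"unknown stage {stage!r}") from exc
    return int(
        np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0]
        % 2**31
    )


@dataclass
class PipelineConfig:
    """Parameters of the full synthetic-cohort analysis run.

    Defaults are the study's analysis settings: sparsity 0.10-0.34 step
    0.01, 100 rewired nulls, 10,000 group/NBS permutations, NBS primary
    threshold 2.9, C grid 1e-3..1e4, 10x10 nested CV, 1,000 classifier
    permutations.
    """

    seed: int | None = None
    # cohort (synthetic_data CohortSpec overrides)
    cohort: dict = field(default_factory=dict)
    # network construction
    grid_points: int = 256
    # graph metrics
    s_min: float = 0.10
    s_max: float = 0.34
    s_step: float = 0.01
    n_rand: int = 100
    degree_mode: str = "binary"
    # group statistics
    group_n_perm: int = 10_000
    q: float = 0.05
    tail: str = "two"
    # NBS
    t_threshold: float = 2.9
    nbs_n_perm: int = 10_000
    nbs_tail: str = "two"
    # classifier
    k_outer: int = 10
    k_inner: int = 10
    c_grid: tuple[float, ...] = tuple(10.0**k for k in range(-3, 5))
    svm_n_perm: int = 1000
    run_svm_permutation: bool = False
    top_regions: int = 20
    # clinical correlation
    correlation_covariates: tuple[str, ...] = ("age", "sex", "education")
    clinical_variables: tuple[str, ...] = ("duration", "onset_age")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("config must set an explicit seed")
        if not 0 < self.s_min < self.s_max < 1:
            raise ConfigError("need 0 < s_min < s_max < 1")
        if self.s_step <= 0:
            raise ConfigError("s_step must be > 0")
        if self.grid_points < 16:
            raise ConfigError("grid_points must be >= 16")
        if self.n_rand < 0 or self.group_n_perm < 100 or self.nbs_n_perm < 100:
            raise ConfigError("permutation/null counts out of range")
        if not 0 < self.q < 1:
            raise ConfigError("q must lie in (0, 1)")
        if self.t_threshold <= 0:
            raise ConfigError("t_threshold must be > 0")
        if self.k_outer < 2 or self.k_inner < 2 or not self.c_grid:
            raise ConfigError("invalid cross-validation settings")
        if self.tail not in ("two", "greater", "less"):
            raise ConfigError(f"unknown tail {self.tail!r}")

    def stage_seed(self, stage: str) -> int:
        return stage_seed(int(self.seed), stage)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["c_grid"] = list(self.c_grid)
        d["correlation_covariates"] = list(self.correlation_covariates)
        d["clinical_variables"] = list(self.clinical_variables)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("c_grid", "correlation_covariates", "clinical_variables"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def setup_logging(verbosity: int = 0) -> None:
    level = (
        logging.WARNING if verbosity < 0
        else logging.INFO if verbosity == 0
        else logging.DEBUG
    )
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )
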